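# Reference structures

Place `1ejg.pdb`, `1qau.pdb` and `148l.pdb` here (Crambin, PDZ-domain,
Lysozyme).  With network access:

```sh
python scripts/fetch_pdb.py
```

`scripts/acceptance.py` uses these files for its structure-dependent
targets and omits them (with a note on stderr) when the files are absent.
They are not bundled with the repository.
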