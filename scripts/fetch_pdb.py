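#!/usr/bin/env python
"""Vendor the reference PDB structures into data/pdb/ (needs network).

Downloads 1EJG (Crambin), 1QAU (PDZ-domain) and 148L (Lysozyme) from the
RCSB file server so that scripts/acceptance.py and the full-scale pipeline
can run offline afterwards.
"""

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ("1ejg", "1qau", "148l")
DEST = Path(__file__).resolve().parent.parent / "data" / "pdb"


def main() -> int:
    DEST.mkdir(parents=True, exist_ok=True)
    ok = True
    for acc in ACCESSIONS:
        url = f"https://files.rcsb.org/download/{acc.upper()}.pdb"
        target = DEST / f"{acc}.pdb"
        if target.exists():
            print(f"{target} already present")
            continue
        try:
            urllib.request.urlretrieve(url, target)
            print(f"fetched {url} -> {target}")
        except Exception as exc:  # noqa: BLE001
            print(f"FAILED to fetch {url}: {exc}", file=sys.stderr)
            ok = False
    return 0 if ok else 1


if __name__ == "__main__":
    raise SystemExit(main())
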