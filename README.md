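# rasta

Direct real-space determination of atomistic electron densities from
sparse single-molecule X-ray scattering images, by resolution-annealed
stochastic gradient ascent (RASTA) on an orientation-marginalized Bayesian
posterior.

The electron density is a sum of identical Gaussian beads (one per heavy
atom).  Each scattering image is a short list of photon scattering
vectors recorded at an unknown, uniformly random molecular orientation.
The likelihood marginalizes the orientation: two Ewald-sphere degrees of
freedom via a spherical quadrature of rotations, the beam-axis rotation
exactly as cyclic shifts of a polar intensity grid.  Gradients with
respect to the bead positions are computed by backpropagation through the
tabulated intensity maps.  The optimizer anneals a smoothing scale
`sigma(t)` from coarse to fine: photons at `|k|` are randomly thinned with
keep-probability `exp(-sigma^2 k^2)` — exactly equivalent to imaging the
Gaussian-smoothed density — and positions follow momentum-accelerated
stochastic gradient ascent on the smoothed log-posterior.

## Layout

| module | contents |
| --- | --- |
| `rasta.bead_model` | Gaussian-bead density, closed-form structure factor/intensity, smoothing operator |
| `rasta.scatter_geometry` | beam parameters, Ewald-sphere polar grid with exact cell areas, orientation quadrature, photon binning |
| `rasta.forward_sim` | photon-level image simulator; physical-beam → effective-intensity conversion |
| `rasta.likelihood` | orientation-marginalized log-likelihood on intensity maps; analytic position gradients |
| `rasta.prior` | bead-position prior (short-range repulsion + smooth connectivity) and gradient |
| `rasta.optimize` | annealing schedules, photon thinning, momentum updates, full run loop |
| `rasta.evaluation` | symmetry-aware rigid alignment (incl. enantiomer search), FSC with 0.5-cutoff resolution, exact earth-mover's distance |
| `rasta.io_cli` | photon-list formats (text + npz), PDB input, toy-molecule fixtures, config schema, CLI |

Conventions: Å and Å⁻¹ everywhere; beam along +z; angular scattering
vectors (`|k_in| = 2π/λ`); resolution `d = 2π/|k|`; Fourier sign
`exp(+i k·r)`; 0-based image and grid indices.

## CLI

```sh
rasta fixtures --kind random-cluster --m 8 --spacing 3 --seed 1 --out toy.pdb
rasta simulate --config cfg.yaml --structure toy.pdb -n 10000 --seed 2 --out photons.txt
rasta loglik   --config cfg.yaml --images photons.txt --structure toy.pdb
rasta reconstruct --config cfg.yaml --images photons.txt --out-dir run/
rasta evaluate --model run/reconstruction.pdb --reference toy.pdb --out-dir eval/
```

`cfg.yaml` is schema-validated (unknown keys rejected); every numeric
default lives in `rasta/io_cli/config.py`.  Runs write a provenance block
(config, seeds, version) sufficient to reproduce outputs bit-for-bit.
Reconstruction outputs: `reconstruction.pdb` (bead pseudo-atoms, readable
by standard viewers), per-step `metrics.tsv`, optional
`checkpoint_sigma*.pdb` snapshots at configured smoothing thresholds.

## Photon-list format

Text dialect: `# key: value` header lines (format/version, beam
parameters, `n_images`, `n_records`, JSON provenance) followed by one
`image_id k_x k_y` row per photon, image ids 0-based and nondecreasing;
empty images are implied by ids without records.  A frozen conformance
vector with its SHA-256 lives in `tests/data/photons_v1_example.txt`.
The `.npz` dialect stores the same schema as columnar arrays plus an
embedded JSON header, for large sets.
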