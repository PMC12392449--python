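"""Photon-level forward simulator for sparse scattering images.

Each image corresponds to one molecule in a uniformly random orientation
``R``.  The photon count is Poisson with mean ``i0_eff * lam(R)`` where
``lam(R)`` is the intensity integral over the (rotated) Ewald cap, and
photon positions are i.i.d. on the cap with density proportional to
``I(R k)``.  Photons are recorded by their transverse components
``(k_x, k_y)``.

Sampling is done on a fine polar tabulation of the intensity over the cap:
cells are drawn with probability proportional to ``I * area`` and positions
are uniform within the cell with respect to the Ewald surface measure
(i.e. uniform in ``(q**2, phi)``).  The tabulation grid is configurable;
its resolution bounds the fidelity of the photon positions (one cell), not
of the photon counts, which use the same quadrature as the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from rasta.bead_model import BeadModel, intensity
from rasta.scatter_geometry import (
    BeamParams,
    OrientationQuadrature,
    PolarGrid,
    kvec_from_q_phi,
)

__all__ = [
    "ScatteringImage",
    "ImageSet",
    "simulate_image",
    "simulate_imageset",
    "expected_photon_count",
    "i0_from_physical_beam",
    "CLASSICAL_ELECTRON_RADIUS_A",
]

#: Thomson scattering length of the electron, in Å.
CLASSICAL_ELECTRON_RADIUS_A = 2.8179403262e-5


@dataclass(frozen=True)
class ScatteringImage:
    """One image: ``n >= 0`` photons as transverse scattering vectors.

    ``photons`` has shape (n, 2) in Å⁻¹; ``n`` may be zero.
    """

    photons: np.ndarray

    def __post_init__(self) -> None:
        ph = np.asarray(self.photons, dtype=np.float64).reshape(-1, 2)
        if not np.all(np.isfinite(ph)):
            raise ValueError("photon coordinates must be finite")
        object.__setattr__(self, "photons", ph)

    @property
    def n_photons(self) -> int:
        return self.photons.shape[0]


@dataclass
class ImageSet:
    """Ordered collection of images with the beam they were recorded under."""

    images: list[ScatteringImage]
    beam: BeamParams
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.images) < 1:
            raise ValueError("an ImageSet needs at least one image")

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterable[ScatteringImage]:
        return iter(self.images)

    def __getitem__(self, i):
        return self.images[i]

    @property
    def n_photons_total(self) -> int:
        return sum(im.n_photons for im in self.images)


def i0_from_physical_beam(
    photons_per_pulse: float,
    beam_diameter: float,
    wavelength: float,
) -> float:
    """Effective intensity scale from physical beam parameters.

    The expected number of photons scattered into solid angle ``dOmega``
    by a density with Fourier transform ``rho_hat`` is
    ``fluence * r_e**2 * |rho_hat(k)|**2 * dOmega`` (Thomson scattering,
    polarization factor omitted), with ``fluence = photons_per_pulse /
    (pi * (beam_diameter/2)**2)``.  A solid-angle element corresponds to
    the Ewald-surface area element ``dA = R_E**2 dOmega`` with
    ``R_E = 2*pi/wavelength``, so expected counts are
    ``i0_eff * integral_E |rho_hat|**2 dA`` with::

        i0_eff = fluence * r_e**2 / R_E**2

    Parameters are in Å (`beam_diameter`, `wavelength`); the result has
    units Å² so that ``i0_eff * lambda_l`` is dimensionless.
    """
    if photons_per_pulse <= 0 or beam_diameter <= 0 or wavelength <= 0:
        raise ValueError("beam parameters must be positive")
    fluence = photons_per_pulse / (np.pi * (beam_diameter / 2.0) ** 2)
    ewald_radius = 2.0 * np.pi / wavelength
    return fluence * CLASSICAL_ELECTRON_RADIUS_A**2 / ewald_radius**2


def _cap_lambda(model: BeadModel, grid: PolarGrid, rotation: np.ndarray) -> float:
    """Intensity integral over the Ewald cap for one orientation."""
    pts = grid.centers.reshape(-1, 3) @ rotation.T
    vals = intensity(model, pts)
    return float(np.sum(vals * grid.areas.ravel()))


def expected_photon_count(
    model: BeadModel,
    beam: BeamParams,
    quad: OrientationQuadrature,
    grid: PolarGrid,
) -> float:
    """Orientation-averaged expected photon count per image.

    ``E_R[i0_eff * lam(R)]`` approximated with the orientation quadrature
    and the polar-grid cell areas.
    """
    lam = 0.0
    for R, w in zip(quad.rotations, quad.weights):
        lam += w * _cap_lambda(model, grid, R)
    return beam.i0_eff * lam


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform rotations from uniformly distributed unit quaternions."""
    quat = rng.standard_normal((n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    w, x, y, z = quat.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def _sample_photons_for_rotation(
    model: BeadModel,
    grid: PolarGrid,
    rotation: np.ndarray,
    n_photons: int,
    rng: np.random.Generator,
    cell_probs: np.ndarray,
) -> np.ndarray:
    """Draw photon transverse positions given the per-cell probabilities."""
    if n_photons == 0:
        return np.empty((0, 2))
    cells = rng.choice(grid.n_cells, size=n_photons, p=cell_probs)
    r_idx, s_idx = np.divmod(cells, grid.n_s)
    # uniform w.r.t. surface measure within the cell: uniform in (q^2, phi)
    q2_lo = grid.q_edges[r_idx] ** 2
    q2_hi = grid.q_edges[r_idx + 1] ** 2
    q = np.sqrt(q2_lo + rng.random(n_photons) * (q2_hi - q2_lo))
    phi = (s_idx + rng.random(n_photons)) * grid.dphi
    kvec = kvec_from_q_phi(q, phi, grid.ewald_radius)
    return kvec[:, :2]


def simulate_image(
    model: BeadModel,
    beam: BeamParams,
    rng: np.random.Generator,
    sim_grid: PolarGrid | None = None,
) -> ScatteringImage:
    """Simulate a single image at a uniformly random orientation."""
    if sim_grid is None:
        sim_grid = PolarGrid(
            n_r=64, n_s=64, kmax=beam.kmax, ewald_radius=beam.ewald_radius
        )
    R = _random_rotations(rng, 1)[0]
    pts = sim_grid.centers.reshape(-1, 3) @ R.T
    vals = intensity(model, pts)
    masses = vals * sim_grid.areas.ravel()
    lam = float(masses.sum())
    n = int(rng.poisson(beam.i0_eff * lam))
    if lam <= 0.0:
        return ScatteringImage(photons=np.empty((0, 2)))
    photons = _sample_photons_for_rotation(
        model, sim_grid, R, n, rng, masses / lam
    )
    return ScatteringImage(photons=photons)


def simulate_imageset(
    model: BeadModel,
    beam: BeamParams,
    n_images: int,
    seed: int,
    sim_grid: PolarGrid | None = None,
    chunk_size: int = 256,
) -> ImageSet:
    """Simulate `n_images` independent images, bit-reproducible given `seed`.

    Orientation sampling, counts and photon positions are vectorized in
    chunks of `chunk_size` images for speed; the result is identical to
    repeated :func:`simulate_image` draws only in distribution, but is
    deterministic for a given (seed, chunk_size, grid).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if sim_grid is None:
        sim_grid = PolarGrid(
            n_r=64, n_s=64, kmax=beam.kmax, ewald_radius=beam.ewald_radius
        )
    rng = np.random.default_rng(seed)
    ref_pts = sim_grid.centers.reshape(-1, 3)
    areas = sim_grid.areas.ravel()
    images: list[ScatteringImage] = []
    for lo in range(0, n_images, chunk_size):
        n_chunk = min(chunk_size, n_images - lo)
        rots = _random_rotations(rng, n_chunk)
        # (n_chunk * n_cells, 3) rotated evaluation points
        pts = np.einsum("cij,nj->cni", rots, ref_pts).reshape(-1, 3)
        vals = intensity(model, pts).reshape(n_chunk, -1)
        masses = vals * areas[None, :]
        lams = masses.sum(axis=1)
        counts = rng.poisson(beam.i0_eff * lams)
        for c in range(n_chunk):
            if lams[c] <= 0.0 or counts[c] == 0:
                images.append(ScatteringImage(photons=np.empty((0, 2))))
                continue
            photons = _sample_photons_for_rotation(
                model, sim_grid, rots[c], int(counts[c]), rng,
                masses[c] / lams[c],
            )
            images.append(ScatteringImage(photons=photons))
    provenance = {
        "generator": "rasta.forward_sim.simulate_imageset",
        "seed": int(seed),
        "n_images": int(n_images),
        "sim_grid": {"n_r": sim_grid.n_r, "n_s": sim_grid.n_s},
        "chunk_size": int(chunk_size),
        "model": {"m": model.m, "height": model.height, "width": model.width},
    }
    return ImageSet(images=images, beam=beam, provenance=provenance)
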