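"""Gaussian-bead representation of the electron density.

A molecule is represented as a sum of ``m`` identical isotropic Gaussian
beads with common height ``h`` (electrons per bead) and common width
parameter ``w`` (Å⁻¹, acting as a precision: larger ``w`` means a narrower
bead)::

    rho(r) = sum_i  h * (w / sqrt(2*pi))**3 * exp(-0.5 * w**2 * |r - y_i|**2)

Each bead integrates to exactly ``h`` electrons, so the total integrated
density is ``m * h``.  The Fourier transform (sign convention
``exp(+i k·r)``) is closed-form::

    rho_hat(k) = h * exp(-|k|**2 / (2 w**2)) * sum_i exp(i k·y_i)

and the scattering intensity is ``I(k) = |rho_hat(k)|**2``, which is
invariant under global translation of the beads and under ``k -> -k``
(Friedel symmetry).

Smoothing by convolution with an isotropic Gaussian kernel of standard
deviation ``sigma`` (Å) keeps positions and heights and widens the beads:
``1/w'**2 = 1/w**2 + sigma**2``.  Equivalently it multiplies the structure
factor by ``exp(-sigma**2 |k|**2 / 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BeadModel",
    "SmoothingKernel",
    "default_width_for_fwhm",
    "evaluate_density",
    "structure_factor",
    "intensity",
    "smooth",
]

#: FWHM of a Gaussian with unit standard deviation.
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class InvalidModelError(ValueError):
    """Raised for bead models violating positivity/finiteness invariants."""


def default_width_for_fwhm(fwhm: float = 2.0) -> float:
    """Width (precision) parameter giving a bead density FWHM of `fwhm` Å.

    The bead density has standard deviation ``1/w``, so
    ``w = 2*sqrt(2*ln 2) / fwhm``.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    return _FWHM_PER_SIGMA / fwhm


@dataclass(frozen=True)
class BeadModel:
    """Electron density as ``m`` identical Gaussian beads.

    Parameters
    ----------
    positions : (m, 3) array
        Bead centers ``y_i`` in Å.
    height : float
        Electrons per bead, ``h > 0``.
    width : float
        Precision parameter ``w > 0`` in Å⁻¹ (bead std is ``1/w``).
    """

    positions: np.ndarray
    height: float = 7.0
    width: float = _FWHM_PER_SIGMA / 2.0  # FWHM = 2 Å

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise InvalidModelError(
                f"positions must have shape (m, 3) with m >= 1, got {pos.shape}"
            )
        if not np.all(np.isfinite(pos)):
            raise InvalidModelError("positions must be finite")
        if not (np.isfinite(self.height) and self.height > 0):
            raise InvalidModelError(f"height must be positive, got {self.height}")
        if not (np.isfinite(self.width) and self.width > 0):
            raise InvalidModelError(f"width must be positive, got {self.width}")
        object.__setattr__(self, "positions", pos)

    @property
    def m(self) -> int:
        """Number of beads."""
        return self.positions.shape[0]

    @property
    def total_density(self) -> float:
        """Integral of the density over all space, ``m * h`` electrons."""
        return self.m * self.height

    @property
    def fwhm(self) -> float:
        """FWHM of a single bead in Å."""
        return _FWHM_PER_SIGMA / self.width

    def with_positions(self, positions: np.ndarray) -> "BeadModel":
        """Same height/width, new bead centers."""
        return BeadModel(positions=positions, height=self.height, width=self.width)


@dataclass(frozen=True)
class SmoothingKernel:
    """Isotropic Gaussian convolution kernel with std ``sigma`` (Å).

    ``sigma = 0`` is the identity smoothing.
    """

    sigma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def evaluate_density(model: BeadModel, points: np.ndarray) -> np.ndarray:
    """Evaluate the bead density at `points` ((n, 3), Å) in electrons/Å³."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    # |r - y_i|^2 via broadcasting; n x m can be large, chunk over points
    prefactor = model.height * (model.width / np.sqrt(2.0 * np.pi)) ** 3
    out = np.zeros(pts.shape[0])
    chunk = max(1, int(2**22 // max(model.m, 1)))
    for lo in range(0, pts.shape[0], chunk):
        d2 = np.sum(
            (pts[lo : lo + chunk, None, :] - model.positions[None, :, :]) ** 2, axis=2
        )
        out[lo : lo + chunk] = prefactor * np.sum(
            np.exp(-0.5 * model.width**2 * d2), axis=1
        )
    return out


def structure_factor(model: BeadModel, kpoints: np.ndarray) -> np.ndarray:
    """Closed-form Fourier transform ``rho_hat(k)`` at `kpoints` ((n, 3), Å⁻¹).

    Sign convention: ``rho_hat(k) = integral rho(r) exp(+i k·r) dr``.
    """
    kpts = np.atleast_2d(np.asarray(kpoints, dtype=np.float64))
    if not np.all(np.isfinite(kpts)):
        raise ValueError("kpoints must be finite")
    k2 = np.sum(kpts**2, axis=1)
    envelope = model.height * np.exp(-k2 / (2.0 * model.width**2))
    out = np.empty(kpts.shape[0], dtype=np.complex128)
    chunk = max(1, int(2**22 // max(model.m, 1)))
    for lo in range(0, kpts.shape[0], chunk):
        phases = np.exp(1j * (kpts[lo : lo + chunk] @ model.positions.T))
        out[lo : lo + chunk] = phases.sum(axis=1)
    out *= envelope
    return out


def intensity(model: BeadModel, kpoints: np.ndarray) -> np.ndarray:
    """Scattering intensity ``I(k) = |rho_hat(k)|**2`` (nonnegative)."""
    f = structure_factor(model, kpoints)
    return (f * f.conj()).real


def smooth(model: BeadModel, kernel: "SmoothingKernel | float") -> BeadModel:
    """Convolve the density with a Gaussian kernel.

    Returns a model with identical positions and height and widened beads,
    ``1/w'**2 = 1/w**2 + sigma**2``.  The structure factor of the result is
    that of the input times ``exp(-sigma**2 k**2 / 2)`` (convolution
    theorem); the intensity picks up ``exp(-sigma**2 k**2)``.
    """
    sigma = kernel.sigma if isinstance(kernel, SmoothingKernel) else float(kernel)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        return model
    w = model.width
    w_new = w / np.sqrt(1.0 + (sigma * w) ** 2)
    return BeadModel(positions=model.positions, height=model.height, width=w_new)
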