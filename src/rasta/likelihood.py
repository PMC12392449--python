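"""Grid-approximated orientation-marginalized log-likelihood and gradient.

For a model with intensity maps ``I[l, r, s] = |rho_hat(R_l q_{r,s})|**2``
tabulated on the orientation quadrature × polar grid, the single-image
likelihood is approximated as::

    P(k_1..k_n | rho) ~= sum_l w_l exp(-I0 * lam_l) * (1/n_s) *
                         sum_{s'} prod_i I[l, r(k_i), (s(k_i) + s') mod n_s]

with ``lam_l = sum_{r,s} a[r,s] * I[l, r, s]``.  The inner sum over the
cyclic angular offset ``s'`` realizes the beam-axis rotation degree of
freedom exactly on the grid.  Constant per-photon factors of ``I0`` are
dropped (they do not depend on the density), so absolute log-likelihood
values are comparable only within one beam/grid configuration.

Everything is evaluated in the log domain: the photon products are sums of
``log I`` and the ``(l, s')`` mixture is collapsed with log-sum-exp, so
images with hundreds of photons and intensities spanning many orders of
magnitude do not overflow.

The gradient with respect to the bead positions is computed by
backpropagation: per-image posterior responsibilities over ``(l, s')``
(the softmax of the log-terms) weight the photon contributions ``1/I`` at
their cells and the exposure contributions ``-I0 * a[r,s]``, giving
``dL/dI[l,r,s]``; the chain rule through the closed-form intensity of the
Gaussian-bead model then yields per-bead 3-vectors.  The cyclic structure
of the ``s'`` sum lets both the photon log-terms and the responsibility
accumulation be evaluated as circular (cross-)correlations along the
angular axis via real FFTs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from rasta.bead_model import BeadModel
from rasta.forward_sim import ImageSet, ScatteringImage
from rasta.scatter_geometry import (
    BeamParams,
    OrientationQuadrature,
    PolarGrid,
    bin_photons,
)

__all__ = [
    "IntensityMaps",
    "LogLikelihoodResult",
    "GradientUndefinedError",
    "compute_intensity_maps",
    "estimate_lambdas",
    "log_likelihood_image",
    "log_likelihood_batch",
    "grad_log_likelihood",
    "grad_from_counts",
]

#: Intensities below this are floored in the log domain for gradients.
INTENSITY_FLOOR = 1e-280


class GradientUndefinedError(RuntimeError):
    """The likelihood is -inf, so its gradient is undefined."""


@dataclass(frozen=True)
class IntensityMaps:
    """Tabulated ``I[l, r, s]`` with the geometry it was built on."""

    values: np.ndarray  # (n_R, n_r, n_s)
    quad: OrientationQuadrature
    grid: PolarGrid

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        expect = (self.quad.n_rotations, self.grid.n_r, self.grid.n_s)
        if vals.shape != expect:
            raise ValueError(f"values shape {vals.shape} != {expect}")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("intensity maps must be finite and nonnegative")
        object.__setattr__(self, "values", vals)


@dataclass
class LogLikelihoodResult:
    """Total log-likelihood (nats), optional per-image terms, and lambdas."""

    total: float
    lambdas: np.ndarray
    per_image: np.ndarray | None = None


def compute_intensity_maps(
    model: BeadModel,
    quad: OrientationQuadrature,
    grid: PolarGrid,
) -> IntensityMaps:
    """Evaluate ``I[l, r, s] = |rho_hat(R_l q_{r,s})|**2``.

    The radial Gaussian envelope depends on ``|k|`` only and is factored
    out; the per-orientation phase sums cost ``O(n_R n_r n_s m)``.
    """
    maps, _ = _maps_with_phases(model, quad, grid, cache_phases=False)
    return maps


#: cache the (rotated cells x beads) phase matrix up to this many entries
_PHASE_CACHE_LIMIT = 2**24


def _maps_with_phases(
    model: BeadModel,
    quad: OrientationQuadrature,
    grid: PolarGrid,
    cache_phases: bool,
) -> tuple[IntensityMaps, "tuple | None"]:
    """Intensity maps, optionally keeping phases/F for the backprop pass."""
    ref = grid.centers.reshape(-1, 3)  # (n_cells, 3)
    q2 = np.sum(ref**2, axis=1)
    env2 = model.height**2 * np.exp(-q2 / model.width**2)  # |A|^2 per cell
    n_R = quad.n_rotations
    total = n_R * grid.n_cells * model.m
    keep = cache_phases and total <= _PHASE_CACHE_LIMIT
    out = np.empty((n_R, grid.n_cells))
    kept_phases = [] if keep else None
    kept_pts = [] if keep else None
    chunk = max(1, int(2**23 // max(grid.n_cells * model.m, 1)))
    for lo in range(0, n_R, chunk):
        rots = quad.rotations[lo : lo + chunk]
        pts = (ref @ rots.transpose(0, 2, 1)).reshape(-1, 3)
        phases = np.exp(1j * (pts @ model.positions.T))
        F = phases.sum(axis=1)
        out[lo : lo + chunk] = (np.abs(F) ** 2).reshape(len(rots), -1) * env2[None, :]
        if keep:
            kept_phases.append((phases, F))
            kept_pts.append(pts)
    maps = IntensityMaps(
        values=out.reshape(n_R, grid.n_r, grid.n_s), quad=quad, grid=grid
    )
    cache = (kept_phases, kept_pts, env2, chunk) if keep else None
    return maps, cache


def estimate_lambdas(maps: IntensityMaps) -> np.ndarray:
    """Per-orientation Ewald-cap integrals ``lam_l = sum a[r,s] I[l,r,s]``."""
    return np.einsum("lrs,rs->l", maps.values, maps.grid.areas)


def _photon_counts(
    images: "list[ScatteringImage] | ImageSet", grid: PolarGrid
) -> np.ndarray:
    """Per-image photon histograms on the polar grid, shape (B, n_r, n_s)."""
    B = len(images)
    counts = np.zeros((B, grid.n_r, grid.n_s))
    for b, im in enumerate(images):
        if im.n_photons == 0:
            continue
        r, s = bin_photons(im.photons, grid)
        np.add.at(counts[b], (r, s), 1.0)
    return counts


def _log_terms(
    counts: np.ndarray, maps: IntensityMaps, beam: BeamParams
) -> np.ndarray:
    """Log-terms ``T[b, l, s']`` of the (l, s') mixture for each image.

    ``T[b,l,s'] = log w_l - I0 lam_l - log n_s
                  + sum_{r,s} counts[b,r,s] * log I[l, r, (s+s') mod n_s]``
    evaluated as a circular cross-correlation along the angular axis.
    """
    n_s = maps.grid.n_s
    log_i = np.log(np.maximum(maps.values, INTENSITY_FLOOR))
    c_hat = np.fft.rfft(counts, axis=-1)  # (B, n_r, f)
    m_hat = np.fft.rfft(log_i, axis=-1)  # (n_R, n_r, f)
    # sum over r per frequency as a batched matmul: (f,B,r) @ (f,r,l)
    prod = c_hat.conj().transpose(2, 0, 1) @ m_hat.transpose(2, 1, 0)
    corr = np.fft.irfft(prod.transpose(1, 2, 0), n=n_s, axis=-1)
    lambdas = estimate_lambdas(maps)
    base = np.log(maps.quad.weights) - beam.i0_eff * lambdas - np.log(n_s)
    return corr + base[None, :, None]


def _check_support(counts: np.ndarray, maps: IntensityMaps) -> bool:
    """True if some photon sits where the map is (numerically) zero for
    every ``(l, s')`` offset, which makes the raw likelihood -inf."""
    dead = maps.values <= 0.0
    if not dead.any():
        return False
    # a photon cell (r, s) is fatal if for every l, s' the shifted map is 0
    occupied = counts.sum(axis=0) > 0  # (n_r, n_s)
    for r in range(maps.grid.n_r):
        if not occupied[r].any():
            continue
        # shifted intensity row: I[l, r, (s + s') % n_s]; fatal iff the whole
        # (l, :) row is zero for all l -> row of zeros independent of s
        if np.all(dead[:, r, :]):
            return True
    return False


def log_likelihood_image(
    image: ScatteringImage, maps: IntensityMaps, beam: BeamParams
) -> float:
    """Log of the grid-approximated single-image likelihood (nats).

    Returns ``-inf`` (with a warning) if some photon has zero intensity
    support under every ``(l, s')``.
    """
    counts = _photon_counts([image], maps.grid)
    if _check_support(counts, maps):
        warnings.warn("photon with zero intensity support: likelihood is -inf")
        return float("-inf")
    T = _log_terms(counts, maps, beam)
    return float(logsumexp(T[0]))


def log_likelihood_batch(
    images: "ImageSet | list[ScatteringImage]",
    model: BeadModel,
    quad: OrientationQuadrature,
    grid: PolarGrid,
    beam: BeamParams,
    keep_per_image: bool = True,
    maps: IntensityMaps | None = None,
) -> LogLikelihoodResult:
    """Joint log-likelihood of a batch (sum over images).

    Maps are computed once per call unless supplied.
    """
    if maps is None:
        maps = compute_intensity_maps(model, quad, grid)
    counts = _photon_counts(images, grid)
    if _check_support(counts, maps):
        warnings.warn("photon with zero intensity support: likelihood is -inf")
        per = np.full(len(images), -np.inf)
        return LogLikelihoodResult(
            total=float("-inf"),
            lambdas=estimate_lambdas(maps),
            per_image=per if keep_per_image else None,
        )
    T = _log_terms(counts, maps, beam)
    per = logsumexp(T.reshape(T.shape[0], -1), axis=1)
    return LogLikelihoodResult(
        total=float(per.sum()),
        lambdas=estimate_lambdas(maps),
        per_image=per if keep_per_image else None,
    )


def _backprop_positions(
    model: BeadModel,
    quad: OrientationQuadrature,
    grid: PolarGrid,
    dL_dI: np.ndarray,
    cache: "tuple | None" = None,
) -> np.ndarray:
    """Chain rule from ``dL/dI[l,r,s]`` to per-bead position gradients.

    With ``I = |A(k)|**2 |F(k)|**2``, ``F = sum_i exp(i k·y_i)``::

        dI/dy_i = -2 |A|**2 Im( conj(F) exp(i k·y_i) ) k

    `cache` (from :func:`_maps_with_phases`) reuses the phase matrices of
    the forward pass when they fit in memory.
    """
    ref = grid.centers.reshape(-1, 3)
    grads = np.zeros((model.m, 3))
    flatG = dL_dI.reshape(quad.n_rotations, -1)
    if cache is not None:
        kept_phases, kept_pts, env2, chunk = cache
    else:
        q2 = np.sum(ref**2, axis=1)
        env2 = model.height**2 * np.exp(-q2 / model.width**2)
        chunk = max(1, int(2**23 // max(grid.n_cells * model.m, 1)))
    for ci, lo in enumerate(range(0, quad.n_rotations, chunk)):
        rots = quad.rotations[lo : lo + chunk]
        if cache is not None:
            phases, F = kept_phases[ci]
            pts = kept_pts[ci]
        else:
            pts = (ref @ rots.transpose(0, 2, 1)).reshape(-1, 3)
            phases = np.exp(1j * (pts @ model.positions.T))  # (n_pts, m)
            F = phases.sum(axis=1)
        weight = flatG[lo : lo + chunk].ravel() * np.tile(env2, len(rots))
        u = weight * F.conj()
        S = np.imag(u[:, None] * phases)  # (n_pts, m)
        grads += -2.0 * (S.T @ pts)
    return grads


def grad_log_likelihood(
    images: "ImageSet | list[ScatteringImage]",
    model: BeadModel,
    quad: OrientationQuadrature,
    grid: PolarGrid,
    beam: BeamParams,
    maps: IntensityMaps | None = None,
) -> tuple[np.ndarray, LogLikelihoodResult]:
    """Gradient of the batch log-likelihood w.r.t. bead positions.

    Returns ``(grads, result)`` with `grads` of shape (m, 3) in Å⁻¹.
    Raises :class:`GradientUndefinedError` when the likelihood is -inf.
    """
    counts = _photon_counts(images, grid)
    return grad_from_counts(counts, model, quad, grid, beam, maps=maps)


def grad_from_counts(
    counts: np.ndarray,
    model: BeadModel,
    quad: OrientationQuadrature,
    grid: PolarGrid,
    beam: BeamParams,
    maps: IntensityMaps | None = None,
) -> tuple[np.ndarray, LogLikelihoodResult]:
    """Like :func:`grad_log_likelihood`, from per-image photon histograms.

    `counts` has shape (B, n_r, n_s); this is the entry point for callers
    that maintain pre-binned photons (the optimizer's inner loop).
    """
    cache = None
    if maps is None:
        maps, cache = _maps_with_phases(model, quad, grid, cache_phases=True)
    if _check_support(counts, maps):
        raise GradientUndefinedError(
            "likelihood is -inf (photon with zero intensity support)"
        )
    T = _log_terms(counts, maps, beam)
    B = T.shape[0]
    per = logsumexp(T.reshape(B, -1), axis=1)
    gamma = np.exp(T - per[:, None, None])  # responsibilities over (l, s')
    # photon term: dL/dlogI[l,r,u] = sum_b (gamma[b,l] (*) counts[b,r])[u]
    n_s = maps.grid.n_s
    g_hat = np.fft.rfft(gamma, axis=-1)
    c_hat = np.fft.rfft(counts, axis=-1)
    # sum over b per frequency: (f,l,B) @ (f,B,r) -> (f,l,r)
    prod = g_hat.transpose(2, 1, 0) @ c_hat.transpose(2, 0, 1)
    conv = np.fft.irfft(prod.transpose(1, 2, 0), n=n_s, axis=-1)
    dL_dI = conv / np.maximum(maps.values, INTENSITY_FLOOR)
    # exposure term: d(-I0 lam_l)/dI = -I0 a[r,s], weighted by Gamma_l
    Gamma = gamma.sum(axis=(0, 2))
    dL_dI -= beam.i0_eff * Gamma[:, None, None] * maps.grid.areas[None, :, :]
    grads = _backprop_positions(model, quad, maps.grid, dL_dI, cache=cache)
    result = LogLikelihoodResult(
        total=float(per.sum()), lambdas=estimate_lambdas(maps), per_image=per
    )
    return grads, result
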