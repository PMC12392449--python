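"""Bead-position prior: short-range repulsion plus smooth connectivity.

The negative log prior is::

    E(y) = sum_{i != j} f1(|y_i - y_j|)
         + sum_i f3( sum_{j != i} f2(|y_i - y_j|) )

with three C¹ ingredients (forms configurable through their parameters):

* ``f1(d) = c1 * softplus((d_rep - d)/s1)**2`` — smooth short-range
  repulsion, negligible beyond ``d_rep`` (softplus decays exponentially);
* ``f2(d) = 1 / (1 + exp((d - r_nb)/s_nb))`` — smooth neighbor indicator,
  monotonically decreasing in distance, ~1 inside ``r_nb``, ~0 outside;
* ``f3(x) = c3 * max(0, n_min - x)**2`` — one-sided penalty that is exactly
  zero once the smooth neighbor count exceeds ``n_min`` (no force on
  well-connected beads).

``log_prior`` returns ``-E``; it is exactly invariant under rigid motion
and bead permutation, and the per-bead gradients sum to zero.
Diagonal (``i = j``) terms are excluded from both sums (they would only
add constants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from rasta.bead_model import BeadModel

__all__ = ["PriorParams", "log_prior", "grad_log_prior"]


@dataclass(frozen=True)
class PriorParams:
    """Parameters of the repulsion + connectivity prior.

    Distances in Å; strengths dimensionless (nats at unit violation).
    """

    d_rep: float = 1.0  # repulsion range
    c1: float = 10.0  # repulsion strength
    s1: float = 0.2  # repulsion smoothness
    r_nb: float = 4.5  # neighbor radius
    s_nb: float = 0.5  # neighbor-count smoothness
    n_min: float = 2.0  # minimum smooth neighbor count
    c3: float = 1.0  # connectivity strength

    def __post_init__(self) -> None:
        if min(self.d_rep, self.s1, self.r_nb, self.s_nb) <= 0:
            raise ValueError("distances and smoothness scales must be positive")
        if self.c1 < 0 or self.c3 < 0:
            raise ValueError("strengths must be nonnegative")
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _pair_distances(positions: np.ndarray) -> np.ndarray:
    diff = positions[:, None, :] - positions[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=2)), diff


def log_prior(model: BeadModel, params: PriorParams) -> float:
    """Log prior (nats, up to an additive constant): ``-E(y)``."""
    d, _ = _pair_distances(model.positions)
    m = model.m
    off = ~np.eye(m, dtype=bool)
    sp = _softplus((params.d_rep - d) / params.s1)
    e1 = params.c1 * np.sum(sp[off] ** 2)
    f2 = expit((params.r_nb - d) / params.s_nb)
    np.fill_diagonal(f2, 0.0)
    counts = f2.sum(axis=1)
    deficit = np.maximum(0.0, params.n_min - counts)
    e3 = params.c3 * np.sum(deficit**2)
    return float(-(e1 + e3))


def grad_log_prior(model: BeadModel, params: PriorParams) -> np.ndarray:
    """Analytic gradient of :func:`log_prior`, shape (m, 3).

    Per-bead gradients sum to zero exactly (translation invariance).
    """
    d, diff = _pair_distances(model.positions)
    m = model.m
    eye = np.eye(m, dtype=bool)
    d_safe = np.where(eye | (d == 0.0), 1.0, d)
    unit = diff / d_safe[:, :, None]

    x1 = (params.d_rep - d) / params.s1
    sp = _softplus(x1)
    # dE1/dy_i = sum_j 2 f1'(d_ij) unit_ij; f1' = -2 c1 sp sigmoid / s1
    f1p = -2.0 * params.c1 * sp * expit(x1) / params.s1
    np.fill_diagonal(f1p, 0.0)

    f2 = expit((params.r_nb - d) / params.s_nb)
    np.fill_diagonal(f2, 0.0)
    counts = f2.sum(axis=1)
    deficit = np.maximum(0.0, params.n_min - counts)
    f3p = -2.0 * params.c3 * deficit  # df3/dcounts
    f2p = -f2 * (1.0 - f2) / params.s_nb  # df2/dd
    np.fill_diagonal(f2p, 0.0)

    pair_coeff = 2.0 * f1p + (f3p[:, None] + f3p[None, :]) * f2p
    dE = np.einsum("ij,ijd->id", pair_coeff, unit)
    return -dE
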