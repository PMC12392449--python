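"""Resolution-annealed stochastic gradient ascent.

Each step ``t`` draws a random batch of images, thins every photon at
``|k|`` with keep-probability ``exp(-sigma(t)**2 |k|**2)``, and evaluates
the gradient of the log-likelihood of the thinned batch under the
Gaussian-smoothed model (width widened by ``sigma(t)``) plus the gradient
of the log prior on the raw positions.  Thinning and smoothing are two
sides of the same identity: images simulated from the smoothed density are
distributionally identical to thinned images from the raw density, so the
thinned batch is a valid sample for the smoothed model.  Updates use
momentum::

    v(t+1) = beta(t) * v(t) + grad_logpost
    y(t+1) = y(t) + eta(t) * v(t+1)

The smoothing scale ``sigma(t)`` decreases to zero (default: linearly over
the first ``anneal_fraction`` of the run), after which all photons are
included; the step size stays constant through the anneal and decays
geometrically over the final polish phase, and the momentum factor is
constant by default.  All schedule knobs are configurable and recorded in
the run provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rasta.bead_model import BeadModel, smooth
from rasta.forward_sim import ImageSet, ScatteringImage
from rasta.likelihood import (
    GradientUndefinedError,
    grad_from_counts,
    grad_log_likelihood,
)
from rasta.prior import PriorParams, grad_log_prior
from rasta.scatter_geometry import (
    BeamParams,
    OrientationQuadrature,
    PolarGrid,
    q_from_transverse,
)

__all__ = [
    "AnnealSchedule",
    "OptimizerState",
    "RastaResult",
    "thin_image",
    "rasta_step",
    "run_rasta",
    "initial_model",
]


@dataclass(frozen=True)
class AnnealSchedule:
    """Schedules sigma(t), eta(t), beta(t) plus batching for a run of
    ``total_steps`` steps.

    * ``sigma(t) = sigma0 * max(0, 1 - t / T_anneal)`` with
      ``T_anneal = anneal_fraction * total_steps`` (nonincreasing, exactly
      zero from ``T_anneal`` on);
    * ``eta(t)`` stays at ``eta0`` while annealing is in progress (the
      informative high-|k| photons only enter near the end of the anneal,
      so mobility must be retained until then), then decays geometrically
      from ``eta0`` to ``eta1`` over the remaining polish phase;
    * ``beta(t)`` constant.
    """

    total_steps: int
    sigma0: float = 3.0
    anneal_fraction: float = 0.8
    eta0: float = 1e-3
    eta1: float = 1e-4
    beta: float = 0.9
    batch_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_steps < 0:
            raise ValueError("total_steps must be >= 0")
        if self.sigma0 < 0 or not (0 < self.anneal_fraction <= 1):
            raise ValueError("invalid annealing parameters")
        if self.eta0 <= 0 or self.eta1 <= 0:
            raise ValueError("step sizes must be positive")
        if not (0 <= self.beta < 1):
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def sigma(self, t: int) -> float:
        t_anneal = self.anneal_fraction * self.total_steps
        if t_anneal <= 0:
            return 0.0
        return self.sigma0 * max(0.0, 1.0 - t / t_anneal)

    def eta(self, t: int) -> float:
        t_anneal = self.anneal_fraction * self.total_steps
        if t <= t_anneal or self.total_steps <= 1:
            return self.eta0
        frac = (t - t_anneal) / max(self.total_steps - t_anneal, 1.0)
        return self.eta0 * (self.eta1 / self.eta0) ** min(frac, 1.0)

    def beta_at(self, t: int) -> float:
        return self.beta


@dataclass
class OptimizerState:
    """Current model, per-bead velocities (Å/step), step index and rng."""

    model: BeadModel
    velocities: np.ndarray
    t: int
    rng: np.random.Generator

    def __post_init__(self) -> None:
        v = np.asarray(self.velocities, dtype=np.float64)
        if v.shape != self.model.positions.shape:
            raise ValueError("velocities must be shaped like positions")
        self.velocities = v


@dataclass
class RastaResult:
    """Final model plus per-step metrics and sigma-threshold checkpoints."""

    model: BeadModel
    metrics: list[dict]
    checkpoints: dict[float, BeadModel] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def thin_image(
    image: ScatteringImage, sigma: float, rng: np.random.Generator,
    ewald_radius: float,
) -> ScatteringImage:
    """Bernoulli-thin photons with keep-probability ``exp(-sigma**2 |k|**2)``.

    ``|k|`` is the full 3D scattering-vector norm recovered from the
    transverse components via the Ewald condition.  Order is preserved;
    ``sigma = 0`` keeps every photon.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0 or image.n_photons == 0:
        return image
    q2 = q_from_transverse(image.photons, ewald_radius) ** 2
    keep = rng.random(image.n_photons) < np.exp(-(sigma**2) * q2)
    return ScatteringImage(photons=image.photons[keep])


def initial_model(
    m: int,
    radius_of_gyration: float,
    seed: int,
    height: float,
    width: float,
) -> BeadModel:
    """Random Gaussian cloud with the requested radius of gyration."""
    rng = np.random.default_rng(seed)
    pos = rng.standard_normal((m, 3))
    pos -= pos.mean(axis=0)
    rg = np.sqrt(np.mean(np.sum(pos**2, axis=1)))
    pos *= radius_of_gyration / rg
    return BeadModel(positions=pos, height=height, width=width)


def rasta_step(
    state: OptimizerState,
    batch: "list[ScatteringImage]",
    schedule: AnnealSchedule,
    quad: OrientationQuadrature,
    grid: PolarGrid,
    beam: BeamParams,
    prior_params: PriorParams,
) -> tuple[OptimizerState, dict]:
    """One annealed stochastic ascent step; returns (new state, metrics).

    The incoming state is not mutated.  A step whose gradient is undefined
    (likelihood -inf on the thinned batch) is rejected: the returned state
    advances ``t`` but keeps positions and velocities, and the metrics
    record the rejection.
    """
    if len(batch) == 0:
        raise ValueError("batch must be nonempty")
    t = state.t
    sigma = schedule.sigma(t)
    eta = schedule.eta(t)
    beta = schedule.beta_at(t)
    thinned = [
        thin_image(im, sigma, state.rng, beam.ewald_radius) for im in batch
    ]
    model_s = smooth(state.model, sigma)
    try:
        g_lik, res = grad_log_likelihood(thinned, model_s, quad, grid, beam)
    except GradientUndefinedError:
        metrics = {
            "step": t, "sigma": sigma, "eta": eta, "loglik": float("-inf"),
            "grad_norm": float("nan"), "rejected": True,
        }
        return (
            OptimizerState(
                model=state.model, velocities=state.velocities,
                t=t + 1, rng=state.rng,
            ),
            metrics,
        )
    g_prior = grad_log_prior(state.model, prior_params)
    g = g_lik + g_prior
    v_new = beta * state.velocities + g
    pos_new = state.model.positions + eta * v_new
    metrics = {
        "step": t,
        "sigma": sigma,
        "eta": eta,
        "loglik": res.total,
        "grad_norm": float(np.linalg.norm(g)),
        "rejected": False,
    }
    new_state = OptimizerState(
        model=state.model.with_positions(pos_new),
        velocities=v_new,
        t=t + 1,
        rng=state.rng,
    )
    return new_state, metrics


class _PackedPhotons:
    """Pre-binned photons of a whole image set for the fast run loop.

    Bins and ``|k|**2`` never change during a run, so they are computed
    once; per-step thinning and histogramming are then pure array ops.
    """

    def __init__(self, imageset: ImageSet, grid: PolarGrid) -> None:
        from rasta.scatter_geometry import bin_photons

        sizes = np.array([im.n_photons for im in imageset], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(sizes)])
        self.n_images = len(imageset)
        self.grid = grid
        if self.offsets[-1] == 0:
            self.cell = np.empty(0, dtype=np.int64)
            self.q2 = np.empty(0)
            return
        k = np.vstack([im.photons for im in imageset if im.n_photons])
        r, s = bin_photons(k, grid)
        self.cell = r * grid.n_s + s
        self.q2 = q_from_transverse(k, grid.ewald_radius) ** 2

    def batch_counts(
        self, idx: np.ndarray, sigma: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Thinned per-image histograms (B, n_r, n_s) for image indices.

        Photon thinning draws one uniform per *selected* photon, so the
        randomness matches independent Bernoulli thinning per step.
        """
        B = idx.shape[0]
        lens = self.offsets[idx + 1] - self.offsets[idx]
        total = int(lens.sum())
        n_cells = self.grid.n_r * self.grid.n_s
        if total == 0:
            return np.zeros((B, self.grid.n_r, self.grid.n_s))
        # gather photon indices of the batch
        starts = np.repeat(self.offsets[idx], lens)
        within = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
        ph = starts + within
        img_of = np.repeat(np.arange(B), lens)
        if sigma > 0.0:
            keep = rng.random(total) < np.exp(-(sigma**2) * self.q2[ph])
            ph = ph[keep]
            img_of = img_of[keep]
        flat = np.bincount(
            img_of * n_cells + self.cell[ph], minlength=B * n_cells
        ).astype(np.float64)
        return flat.reshape(B, self.grid.n_r, self.grid.n_s)


def run_rasta(
    imageset: ImageSet,
    model0: BeadModel,
    schedule: AnnealSchedule,
    quad: OrientationQuadrature,
    grid: PolarGrid,
    beam: BeamParams | None = None,
    prior_params: PriorParams | None = None,
    checkpoint_sigmas: tuple[float, ...] = (),
    callback=None,
) -> RastaResult:
    """Run the full annealed ascent for ``schedule.total_steps`` steps.

    Batches are drawn uniformly with replacement each step.  The run is
    bit-reproducible given ``schedule.seed``.  ``checkpoint_sigmas`` are
    smoothing thresholds; the model is snapshotted the first time
    ``sigma(t)`` drops to or below each one.
    """
    if beam is None:
        beam = imageset.beam
    if prior_params is None:
        prior_params = PriorParams()
    rng = np.random.default_rng(schedule.seed)
    state = OptimizerState(
        model=model0,
        velocities=np.zeros_like(model0.positions),
        t=0,
        rng=rng,
    )
    metrics: list[dict] = []
    checkpoints: dict[float, BeadModel] = {}
    pending = sorted(set(checkpoint_sigmas), reverse=True)
    n_img = len(imageset)
    packed = _PackedPhotons(imageset, grid)
    for _ in range(schedule.total_steps):
        idx = rng.integers(0, n_img, size=min(schedule.batch_size, n_img))
        t = state.t
        sigma = schedule.sigma(t)
        eta = schedule.eta(t)
        beta = schedule.beta_at(t)
        counts = packed.batch_counts(idx, sigma, rng)
        model_s = smooth(state.model, sigma)
        try:
            g_lik, res = grad_from_counts(
                counts, model_s, quad, grid, beam
            )
        except GradientUndefinedError:
            step_metrics = {
                "step": t, "sigma": sigma, "eta": eta,
                "loglik": float("-inf"), "grad_norm": float("nan"),
                "rejected": True,
            }
            state = OptimizerState(
                model=state.model, velocities=state.velocities,
                t=t + 1, rng=rng,
            )
            metrics.append(step_metrics)
            continue
        g = g_lik + grad_log_prior(state.model, prior_params)
        v_new = beta * state.velocities + g
        pos_new = state.model.positions + eta * v_new
        state = OptimizerState(
            model=state.model.with_positions(pos_new),
            velocities=v_new, t=t + 1, rng=rng,
        )
        step_metrics = {
            "step": t, "sigma": sigma, "eta": eta, "loglik": res.total,
            "grad_norm": float(np.linalg.norm(g)), "rejected": False,
        }
        metrics.append(step_metrics)
        while pending and schedule.sigma(state.t) <= pending[0]:
            checkpoints[pending.pop(0)] = state.model
        if callback is not None:
            callback(state, step_metrics)
    provenance = {
        "schedule": {
            "total_steps": schedule.total_steps,
            "sigma0": schedule.sigma0,
            "anneal_fraction": schedule.anneal_fraction,
            "eta0": schedule.eta0,
            "eta1": schedule.eta1,
            "beta": schedule.beta,
            "batch_size": schedule.batch_size,
            "seed": schedule.seed,
        },
        "n_images": n_img,
        "prior": vars(prior_params) if hasattr(prior_params, "__dict__")
        else {f: getattr(prior_params, f) for f in prior_params.__dataclass_fields__},
    }
    return RastaResult(
        model=state.model,
        metrics=metrics,
        checkpoints=checkpoints,
        provenance=provenance,
    )
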