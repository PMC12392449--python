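"""Independent oracles used by the test suite.

Everything here is deliberately brute-force and kept independent of the
code paths it checks: numerical quadrature for Fourier transforms,
explicit loops for the mixture likelihood, Monte-Carlo rotation averaging
for the exact orientation integral, and central finite differences for
gradients.
"""

import numpy as np

from rasta.bead_model import evaluate_density, intensity
from rasta.scatter_geometry import bin_photons


def numeric_structure_factor(model, kpoints, extent=6.0, n=96):
    """Brute-force Fourier integral of the gridded density."""
    lo = model.positions.min(axis=0) - extent
    hi = model.positions.max(axis=0) + extent
    axes = [np.linspace(lo[d], hi[d], n) for d in range(3)]
    dv = np.prod([(a[1] - a[0]) for a in axes])
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    rho = evaluate_density(model, pts)
    out = np.empty(len(kpoints), dtype=np.complex128)
    for i, k in enumerate(np.atleast_2d(kpoints)):
        out[i] = np.sum(rho * np.exp(1j * pts @ k)) * dv
    return out


def eq_mixture_loglik_bruteforce(image, maps, beam):
    """Explicit triple loop over (l, s', photons) for the grid likelihood."""
    I = maps.values
    n_R, n_r, n_s = I.shape
    lambdas = np.array(
        [np.sum(maps.grid.areas * I[l]) for l in range(n_R)]
    )
    r_idx, s_idx = bin_photons(image.photons, maps.grid) if image.n_photons else (
        np.empty(0, dtype=int), np.empty(0, dtype=int))
    total = 0.0
    for l in range(n_R):
        for sp in range(n_s):
            prod = 1.0
            for r, s in zip(r_idx, s_idx):
                prod *= I[l, r, (s + sp) % n_s]
            total += (
                maps.quad.weights[l]
                * np.exp(-beam.i0_eff * lambdas[l])
                * prod
                / n_s
            )
    return np.log(total)


def mc_exact_loglik(image, model, beam, n_rot=20000, cap_grid=None, seed=0):
    """Monte-Carlo estimate of the exact orientation-marginalized
    single-image likelihood (dense random rotations, fine cap quadrature
    for the exposure integral)."""
    from rasta.forward_sim import _random_rotations
    from rasta.scatter_geometry import PolarGrid, q_from_transverse, kvec_from_q_phi

    if cap_grid is None:
        cap_grid = PolarGrid(
            n_r=96, n_s=96, kmax=beam.kmax, ewald_radius=beam.ewald_radius
        )
    rng = np.random.default_rng(seed)
    rots = _random_rotations(rng, n_rot)
    ref = cap_grid.centers.reshape(-1, 3)
    areas = cap_grid.areas.ravel()
    # 3D photon positions on the Ewald sphere
    if image.n_photons:
        kt = image.photons
        q = q_from_transverse(kt, beam.ewald_radius)
        phi = np.arctan2(kt[:, 1], kt[:, 0])
        k3 = kvec_from_q_phi(q, phi, beam.ewald_radius)
    else:
        k3 = np.empty((0, 3))
    logs = np.empty(n_rot)
    for i, R in enumerate(rots):
        lam = float(np.sum(intensity(model, ref @ R.T) * areas))
        logp = -beam.i0_eff * lam
        if len(k3):
            logp += float(np.sum(np.log(intensity(model, k3 @ R.T))))
        logs[i] = logp
    mx = logs.max()
    return float(mx + np.log(np.mean(np.exp(logs - mx))))


def fd_gradient(func, positions, step=1e-4):
    """Central finite differences of a scalar function of (m, 3) points."""
    g = np.zeros_like(positions)
    for i in range(positions.shape[0]):
        for d in range(3):
            for sgn in (1.0, -1.0):
                p = positions.copy()
                p[i, d] += sgn * step
                g[i, d] += sgn * func(p) / (2.0 * step)
    return g


def random_rotation(seed):
    rng = np.random.default_rng(seed)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
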