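import numpy as np
import pytest

from rasta.bead_model import BeadModel, intensity
from rasta.forward_sim import ScatteringImage, simulate_imageset
from rasta.likelihood import (
    compute_intensity_maps,
    estimate_lambdas,
    grad_log_likelihood,
    log_likelihood_batch,
    log_likelihood_image,
)
from rasta.scatter_geometry import (
    build_orientation_quadrature,
    build_polar_grid,
    kvec_from_q_phi,
)

from helpers import (
    eq_mixture_loglik_bruteforce,
    fd_gradient,
    mc_exact_loglik,
    random_rotation,
)


def single_bead(h=5.0, w=1.2):
    return BeadModel(positions=np.zeros((1, 3)), height=h, width=w)


class TestIntensityMaps:
    def test_single_bead_map(self, quad, grid):
        m = single_bead()
        maps = compute_intensity_maps(m, quad, grid)
        expected = m.height**2 * np.exp(-grid.q_centers**2 / m.width**2)
        assert np.allclose(maps.values, expected[None, :, None], rtol=1e-12)

    def test_pointwise_oracle(self, toy4, quad, grid, rng):
        maps = compute_intensity_maps(toy4, quad, grid)
        for _ in range(10):
            l = rng.integers(quad.n_rotations)
            r = rng.integers(grid.n_r)
            s = rng.integers(grid.n_s)
            k = quad.rotations[l] @ grid.centers[r, s]
            assert maps.values[l, r, s] == pytest.approx(
                intensity(toy4, k[None, :])[0], rel=1e-12
            )

    def test_equivariance_under_node_mapping(self, toy4, beam):
        # rotating the model about z by the angular spacing of the phi
        # nodes permutes the quadrature rotations -> re-indexed maps
        quad = build_orientation_quadrature(18)  # t=3, n_phi=6
        grid = build_polar_grid(8, 12, beam)
        ang = 2 * np.pi / 6
        Rz = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]]
        )
        rotated = toy4.with_positions(toy4.positions @ Rz.T)
        a = compute_intensity_maps(toy4, quad, grid).values
        b = compute_intensity_maps(rotated, quad, grid).values
        # each rotated-model map equals some original map re-indexed: a
        # permutation of the nodes combined with a cyclic shift of the
        # angular index (the residual beam-axis rotation)
        tol = 1e-8 * a.max()
        perm_found = 0
        for l in range(18):
            matched = False
            for lp in range(18):
                for shift in range(grid.n_s):
                    if np.abs(np.roll(b[l], shift, axis=1) - a[lp]).max() < tol:
                        matched = True
                        break
                if matched:
                    break
            perm_found += matched
        assert perm_found == 18


class TestLambdas:
    def test_single_bead_closed_form(self, quad, beam):
        grid = build_polar_grid(512, 8, beam)
        m = single_bead(h=3.0, w=1.1)
        lam = estimate_lambdas(compute_intensity_maps(m, quad, grid))
        assert np.ptp(lam) < 1e-10 * lam.mean()
        closed = (
            np.pi * m.height**2 * m.width**2
            * (1 - np.exp(-beam.kmax**2 / m.width**2))
        )
        assert lam[0] == pytest.approx(closed, rel=1e-3)

    def test_quadratic_height_scaling(self, toy4, quad, grid):
        lam1 = estimate_lambdas(compute_intensity_maps(toy4, quad, grid))
        doubled = BeadModel(
            positions=toy4.positions, height=2 * toy4.height, width=toy4.width
        )
        lam2 = estimate_lambdas(compute_intensity_maps(doubled, quad, grid))
        assert np.allclose(lam2, 4 * lam1, rtol=1e-12)


class TestLogLikelihoodImage:
    def test_empty_image(self, toy4, quad, grid, beam):
        maps = compute_intensity_maps(toy4, quad, grid)
        lam = estimate_lambdas(maps)
        expected = np.log(np.sum(quad.weights * np.exp(-beam.i0_eff * lam)))
        val = log_likelihood_image(
            ScatteringImage(photons=np.empty((0, 2))), maps, beam
        )
        assert val == pytest.approx(expected, rel=1e-12)

    def test_cyclic_shift_invariance(self, toy4, quad, grid, beam, images20):
        maps = compute_intensity_maps(toy4, quad, grid)
        im = next(im for im in images20 if im.n_photons >= 2)
        ang = grid.dphi
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shifted = ScatteringImage(photons=im.photons @ rot.T)
        a = log_likelihood_image(im, maps, beam)
        b = log_likelihood_image(shifted, maps, beam)
        assert a == pytest.approx(b, abs=1e-10)

    def test_bruteforce_enumeration_tiny(self, beam):
        # n_R = 2, n_r = n_s = 2, 2 photons: full enumeration oracle
        quad = build_orientation_quadrature(2)
        grid = build_polar_grid(2, 2, beam)
        model = BeadModel(
            positions=np.array([[0.0, 0, 0], [1.5, 0.4, -0.2]]), height=3.0
        )
        maps = compute_intensity_maps(model, quad, grid)
        k1 = kvec_from_q_phi(np.array(0.7), np.array(0.3), beam.ewald_radius)[:2]
        k2 = kvec_from_q_phi(np.array(2.1), np.array(3.9), beam.ewald_radius)[:2]
        im = ScatteringImage(photons=np.vstack([k1, k2]))
        assert log_likelihood_image(im, maps, beam) == pytest.approx(
            eq_mixture_loglik_bruteforce(im, maps, beam), rel=1e-12
        )

    def test_bruteforce_enumeration_random(self, toy4, quad, grid, beam, images20):
        maps = compute_intensity_maps(toy4, quad, grid)
        for im in list(images20)[:5]:
            assert log_likelihood_image(im, maps, beam) == pytest.approx(
                eq_mixture_loglik_bruteforce(im, maps, beam), rel=1e-10
            )

    def test_no_overflow_large_image(self, toy4, quad, grid, beam, rng):
        # 10^3 photons, intensities spanning many orders of magnitude
        from rasta.scatter_geometry import kvec_from_q_phi

        q = rng.uniform(0.01, beam.kmax, size=1000)
        phi = rng.uniform(0, 2 * np.pi, size=1000)
        k = kvec_from_q_phi(q, phi, beam.ewald_radius)[:, :2]
        maps = compute_intensity_maps(toy4, quad, grid)
        val = log_likelihood_image(ScatteringImage(photons=k), maps, beam)
        assert np.isfinite(val)


class TestLogLikelihoodBatch:
    def test_batch_of_one(self, toy4, quad, grid, beam, images20):
        maps = compute_intensity_maps(toy4, quad, grid)
        im = images20[0]
        single = log_likelihood_image(im, maps, beam)
        res = log_likelihood_batch([im], toy4, quad, grid, beam)
        assert res.total == pytest.approx(single, rel=1e-12)

    def test_reorder_invariance(self, toy4, quad, grid, beam, images20):
        a = log_likelihood_batch(images20, toy4, quad, grid, beam)
        rev = list(images20)[::-1]
        b = log_likelihood_batch(rev, toy4, quad, grid, beam)
        assert a.total == pytest.approx(b.total, rel=1e-12)
        assert np.allclose(np.sort(a.per_image), np.sort(b.per_image))
        assert a.total == pytest.approx(a.per_image.sum())

    def test_translation_invariance(self, toy4, quad, grid, beam, images20):
        a = log_likelihood_batch(images20, toy4, quad, grid, beam).total
        shifted = toy4.with_positions(toy4.positions + np.array([2.0, -1.0, 3.0]))
        b = log_likelihood_batch(images20, shifted, quad, grid, beam).total
        assert abs(a - b) < 1e-10 * abs(a)

    def test_rotation_invariance_to_quadrature_tolerance(
        self, toy4, beam, sim_grid
    ):
        quad = build_orientation_quadrature(72)
        grid = build_polar_grid(24, 24, beam)
        iset = simulate_imageset(toy4, beam, 50, seed=21, sim_grid=sim_grid)
        rot = random_rotation(17)
        rotated = toy4.with_positions(toy4.positions @ rot.T)
        a = log_likelihood_batch(iset, toy4, quad, grid, beam).total
        b = log_likelihood_batch(iset, rotated, quad, grid, beam).total
        assert abs(a - b) < 1e-2 * abs(a)

    def test_true_model_beats_jittered(self, toy8, beam, quad, sim_grid):
        grid = build_polar_grid(24, 24, beam)
        iset = simulate_imageset(toy8, beam, 1000, seed=22, sim_grid=sim_grid)
        truth_ll = log_likelihood_batch(iset, toy8, quad, grid, beam).total
        rng = np.random.default_rng(23)
        for _ in range(3):
            jit = toy8.with_positions(
                toy8.positions + 2.0 * rng.standard_normal(toy8.positions.shape)
            )
            assert log_likelihood_batch(iset, jit, quad, grid, beam).total < truth_ll


class TestGradient:
    def test_fd_oracle(self, toy4, quad, grid, beam, images20):
        g, _ = grad_log_likelihood(list(images20), toy4, quad, grid, beam)

        def f(pos):
            return log_likelihood_batch(
                images20, toy4.with_positions(pos), quad, grid, beam
            ).total

        fd = fd_gradient(f, toy4.positions, step=1e-4)
        rel = np.abs(fd - g) / np.maximum(np.abs(fd), 1e-10)
        assert rel.max() < 1e-4

    def test_gradient_sum_vanishes(self, toy4, quad, grid, beam, images20):
        g, _ = grad_log_likelihood(list(images20), toy4, quad, grid, beam)
        assert np.abs(g.sum(axis=0)).max() < 1e-8 * np.abs(g).max()

    def test_symmetric_model_zero_gradient(self, quad, grid, beam, sim_grid):
        m = single_bead(h=20.0)
        iset = simulate_imageset(m, beam, 100, seed=24, sim_grid=sim_grid)
        g, _ = grad_log_likelihood(list(iset), m, quad, grid, beam)
        # gradient of a point-symmetric stationary configuration ~ 0
        assert np.abs(g).max() < 1e-8

    def test_equivariance_under_rotation(self, toy4, beam, sim_grid):
        # generic rotation: holds to quadrature tolerance, which shrinks
        # as the orientation rule is refined
        iset = simulate_imageset(toy4, beam, 30, seed=25, sim_grid=sim_grid)
        rot = random_rotation(29)
        rotated = toy4.with_positions(toy4.positions @ rot.T)
        errs = []
        for n_rot in (72, 200):
            quad = build_orientation_quadrature(n_rot)
            grid = build_polar_grid(24, 24, beam)
            g0, _ = grad_log_likelihood(list(iset), toy4, quad, grid, beam)
            g1, _ = grad_log_likelihood(list(iset), rotated, quad, grid, beam)
            errs.append(
                np.linalg.norm(g1 - g0 @ rot.T) / np.linalg.norm(g0)
            )
        assert errs[-1] < 0.1
        assert errs[-1] < errs[0]

    def test_exact_equivariance_under_symmetry_rotation(self, toy4, beam):
        # z-rotation by a common multiple of the quadrature azimuth and
        # grid angular spacings maps the discretization onto itself
        quad = build_orientation_quadrature(18)  # n_phi = 6
        grid = build_polar_grid(12, 12, beam)  # dphi = 30 deg
        ang = np.pi / 3  # 60 deg: multiple of both spacings
        Rz = np.array(
            [[np.cos(ang), -np.sin(ang), 0],
             [np.sin(ang), np.cos(ang), 0],
             [0, 0, 1.0]]
        )
        iset = simulate_imageset(
            toy4, beam, 20, seed=26,
            sim_grid=build_polar_grid(48, 48, beam),
        )
        g0, _ = grad_log_likelihood(list(iset), toy4, quad, grid, beam)
        rotated = toy4.with_positions(toy4.positions @ Rz.T)
        g1, _ = grad_log_likelihood(list(iset), rotated, quad, grid, beam)
        assert np.allclose(g1, g0 @ Rz.T, rtol=1e-8, atol=1e-10)

    def test_returns_matching_loglik(self, toy4, quad, grid, beam, images20):
        g, res = grad_log_likelihood(list(images20), toy4, quad, grid, beam)
        direct = log_likelihood_batch(images20, toy4, quad, grid, beam)
        assert res.total == pytest.approx(direct.total, rel=1e-12)


def test_exact_so3_oracle_agreement(beam):
    """Grid approximation vs Monte-Carlo estimate of the exact rotation
    integral on a tiny image (slow oracle, loose tolerance)."""
    model = BeadModel(positions=np.array([[0.0, 0, 0], [2.5, 1.0, -0.5]]),
                      height=4.0)
    quad = build_orientation_quadrature(128)
    grid = build_polar_grid(48, 64, beam)
    maps = compute_intensity_maps(model, quad, grid)
    k = kvec_from_q_phi(np.array([0.8, 1.6]), np.array([0.4, 2.2]),
                        beam.ewald_radius)[:, :2]
    im = ScatteringImage(photons=k)
    approx = log_likelihood_image(im, maps, beam)
    exact = mc_exact_loglik(im, model, beam, n_rot=4000, seed=31)
    assert approx == pytest.approx(exact, abs=0.1)
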