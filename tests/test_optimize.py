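import numpy as np
import pytest

from rasta.forward_sim import ScatteringImage, simulate_imageset
from rasta.likelihood import grad_log_likelihood, log_likelihood_batch
from rasta.optimize import (
    AnnealSchedule,
    OptimizerState,
    initial_model,
    rasta_step,
    run_rasta,
    thin_image,
)
from rasta.prior import PriorParams, grad_log_prior
from rasta.scatter_geometry import (
    build_orientation_quadrature,
    build_polar_grid,
    kvec_from_q_phi,
)
from rasta.io_cli import make_toy_molecule


class TestAnnealSchedule:
    def test_validation(self):
        with pytest.raises(ValueError):
            AnnealSchedule(total_steps=10, beta=1.0)
        with pytest.raises(ValueError):
            AnnealSchedule(total_steps=10, eta0=0.0)
        with pytest.raises(ValueError):
            AnnealSchedule(total_steps=-1)

    def test_sigma_profile(self):
        s = AnnealSchedule(total_steps=100, sigma0=2.0, anneal_fraction=0.5)
        sig = np.array([s.sigma(t) for t in range(100)])
        assert np.all(np.diff(sig) <= 0)
        assert s.sigma(0) == 2.0
        assert s.sigma(50) == 0.0
        assert s.sigma(99) == 0.0

    def test_eta_profile(self):
        s = AnnealSchedule(total_steps=100, anneal_fraction=0.5,
                           eta0=1e-2, eta1=1e-4)
        assert s.eta(0) == 1e-2
        assert s.eta(50) == 1e-2  # constant through the anneal
        assert s.eta(99) < 1.2e-4
        etas = [s.eta(t) for t in range(100)]
        assert np.all(np.diff(etas) <= 1e-15)


class TestThinImage:
    def test_sigma_zero_identity(self, rng, beam):
        im = ScatteringImage(photons=rng.normal(scale=0.5, size=(30, 2)))
        assert thin_image(im, 0.0, rng, beam.ewald_radius) is im

    def test_large_sigma_empties(self, rng, beam):
        im = ScatteringImage(photons=rng.uniform(0.5, 1.5, size=(200, 2)))
        out = thin_image(im, 50.0, rng, beam.ewald_radius)
        assert out.n_photons == 0

    def test_keep_fraction_binomial(self, beam):
        # all photons at one |k|: kept fraction within 3 binomial SEs
        rng = np.random.default_rng(5)
        n, sigma = 100_000, 0.7
        k0 = 1.1
        kt = kvec_from_q_phi(np.full(n, k0), rng.uniform(0, 2 * np.pi, n),
                             beam.ewald_radius)[:, :2]
        im = ScatteringImage(photons=kt)
        out = thin_image(im, sigma, rng, beam.ewald_radius)
        p = np.exp(-(sigma**2) * k0**2)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(out.n_photons / n - p) < 3 * se

    def test_order_preserved(self, beam):
        rng = np.random.default_rng(6)
        im = ScatteringImage(photons=rng.normal(scale=0.4, size=(500, 2)))
        out = thin_image(im, 0.5, rng, beam.ewald_radius)
        # kept photons appear in their original order
        idx = []
        pos = 0
        ok = True
        for ph in out.photons:
            found = np.nonzero(np.all(im.photons[pos:] == ph, axis=1))[0]
            if len(found) == 0:
                ok = False
                break
            pos += found[0] + 1
        assert ok


class TestRastaStep:
    def test_beta_zero_velocity_equals_gradient(
        self, toy4, quad, grid, beam, images20
    ):
        sched = AnnealSchedule(total_steps=10, sigma0=0.0001,
                               anneal_fraction=0.01, eta0=1e-3, eta1=1e-3,
                               beta=0.0, batch_size=5)
        state = OptimizerState(
            model=toy4, velocities=np.ones_like(toy4.positions), t=5,
            rng=np.random.default_rng(0),
        )
        batch = list(images20)[:5]
        pp = PriorParams()
        new, metrics = rasta_step(state, batch, sched, quad, grid, beam, pp)
        g_lik, _ = grad_log_likelihood(batch, toy4, quad, grid, beam)
        g = g_lik + grad_log_prior(toy4, pp)
        assert np.allclose(new.velocities, g, rtol=1e-12)
        assert new.t == 6

    def test_manual_arithmetic_oracle(self, quad, grid, beam, sim_grid):
        model = make_toy_molecule("two-bead", 2, spacing=6.0)
        iset = simulate_imageset(model, beam, 5, seed=30, sim_grid=sim_grid)
        sched = AnnealSchedule(total_steps=100, sigma0=0.0001,
                               anneal_fraction=0.01, eta0=2e-3, eta1=2e-3,
                               beta=0.7, batch_size=5)
        v0 = np.full((2, 3), 0.3)
        state = OptimizerState(model=model, velocities=v0.copy(), t=50,
                               rng=np.random.default_rng(1))
        pp = PriorParams()
        new, _ = rasta_step(state, list(iset), sched, quad, grid, beam, pp)
        g_lik, _ = grad_log_likelihood(list(iset), model, quad, grid, beam)
        g = g_lik + grad_log_prior(model, pp)
        v_expect = 0.7 * v0 + g
        assert np.allclose(new.velocities, v_expect, atol=1e-12)
        assert np.allclose(
            new.model.positions, model.positions + 2e-3 * v_expect, atol=1e-12
        )

    def test_empty_batch_rejected(self, toy4, quad, grid, beam):
        sched = AnnealSchedule(total_steps=10)
        state = OptimizerState(model=toy4,
                               velocities=np.zeros_like(toy4.positions),
                               t=0, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            rasta_step(state, [], sched, quad, grid, beam, PriorParams())


class TestRunRasta:
    def test_zero_steps_returns_initial(self, toy4, quad, grid, beam, images20):
        sched = AnnealSchedule(total_steps=0, batch_size=5)
        res = run_rasta(images20, toy4, sched, quad, grid)
        assert res.model is toy4
        assert res.metrics == []

    def test_reproducible(self, toy4, quad, grid, beam, images20):
        sched = AnnealSchedule(total_steps=20, batch_size=5, seed=9,
                               eta0=1e-4, eta1=1e-5)
        a = run_rasta(images20, toy4, sched, quad, grid)
        b = run_rasta(images20, toy4, sched, quad, grid)
        assert np.array_equal(a.model.positions, b.model.positions)

    def test_checkpoints_at_sigma_thresholds(self, toy4, quad, grid, beam, images20):
        sched = AnnealSchedule(total_steps=40, sigma0=2.0, anneal_fraction=0.5,
                               batch_size=5, eta0=1e-5, eta1=1e-6)
        res = run_rasta(images20, toy4, sched, quad, grid,
                        checkpoint_sigmas=(1.0, 0.5))
        assert set(res.checkpoints) == {1.0, 0.5}

    def test_two_bead_recovery(self, beam, sim_grid):
        truth = make_toy_molecule("two-bead", 2, spacing=6.0)
        from rasta.scatter_geometry import BeamParams

        hot = BeamParams(wavelength=2.5, i0_eff=2e-2, kmax=3.0)
        iset = simulate_imageset(truth, hot, 2000, seed=31, sim_grid=sim_grid)
        quad = build_orientation_quadrature(32)
        grid = build_polar_grid(24, 32, hot)
        sched = AnnealSchedule(total_steps=600, sigma0=2.0, anneal_fraction=0.7,
                               eta0=1e-3, eta1=1e-5, beta=0.9,
                               batch_size=128, seed=2)
        m0 = initial_model(2, 3.0, seed=2, height=truth.height,
                           width=truth.width)
        res = run_rasta(iset, m0, sched, quad, grid, hot,
                        PriorParams(r_nb=7.0, n_min=1.0, c3=0.2))
        sep = np.linalg.norm(res.model.positions[1] - res.model.positions[0])
        assert abs(sep - 6.0) < 0.3

    def test_no_information_loss(self, beam):
        # at fixed sigma > 0 every photon is eventually included
        rng = np.random.default_rng(3)
        kt = kvec_from_q_phi(rng.uniform(0.1, 2.0, 50),
                             rng.uniform(0, 2 * np.pi, 50),
                             beam.ewald_radius)[:, :2]
        im = ScatteringImage(photons=kt)
        seen = np.zeros(50, dtype=bool)
        for _ in range(500):
            out = thin_image(im, 0.5, rng, beam.ewald_radius)
            for ph in out.photons:
                seen |= np.all(im.photons == ph, axis=1)
            if seen.all():
                break
        assert seen.all()

    def test_monotone_heldout_trend(self, beam, quad, sim_grid):
        truth = make_toy_molecule("two-bead", 2, spacing=6.0)
        from rasta.scatter_geometry import BeamParams

        hot = BeamParams(wavelength=2.5, i0_eff=2e-2, kmax=3.0)
        grid = build_polar_grid(16, 16, hot)
        train = simulate_imageset(truth, hot, 500, seed=33, sim_grid=sim_grid)
        held = simulate_imageset(truth, hot, 200, seed=34, sim_grid=sim_grid)
        sched = AnnealSchedule(total_steps=300, sigma0=2.0, anneal_fraction=0.7,
                               eta0=1e-3, eta1=1e-5, batch_size=64, seed=4)
        # start clearly off the true separation so there is room to improve
        m0 = initial_model(2, 1.5, seed=4, height=truth.height,
                           width=truth.width)
        res = run_rasta(train, m0, sched, quad, grid, hot,
                        PriorParams(r_nb=7.0, n_min=1.0, c3=0.2))
        ll0 = log_likelihood_batch(held, m0, quad, grid, hot).total
        ll1 = log_likelihood_batch(held, res.model, quad, grid, hot).total
        assert ll1 > ll0
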