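"""NEF: tuning calibration, batch decoders, dynamics embedding."""

import numpy as np
import pytest

from manifold_perturb.nef import (
    NEF_LIF,
    assemble_weights,
    build_nef_network,
    calibrate_gain_bias,
    dynamics_transform,
    estimate_activities,
    nef_simulate,
    relearn_nef,
    sample_evaluation_points,
    solve_decoders,
)
from manifold_perturb.spiking import lif_rate, simulate_lif
from manifold_perturb.targets import (
    draw_encoders,
    make_step_targets,
    oscillator_matrix,
)


class TestCalibration:
    def test_defining_conditions(self):
        tun = calibrate_gain_bias(200, seed=0)
        # drive sits exactly at rheobase at the intercept (the rate's
        # logarithmic onset makes the current the robust quantity)
        drive = tun.gains * tun.intercepts + tun.biases
        assert np.allclose(drive, 1.0, atol=1e-9)
        assert np.all(lif_rate(drive - 1e-6, NEF_LIF) == 0.0)
        at_one = lif_rate(tun.gains + tun.biases, NEF_LIF)
        assert np.allclose(at_one, tun.max_rates, atol=0.5)

    def test_max_rates_within_interval(self):
        tun = calibrate_gain_bias(500, (80.0, 120.0), seed=1)
        assert tun.max_rates.min() >= 80.0
        assert tun.max_rates.max() <= 120.0

    def test_unreachable_rates_rejected(self):
        with pytest.raises(ValueError):
            calibrate_gain_bias(10, (400.0, 600.0), seed=0)


class TestEvaluationPoints:
    def test_box_domain_and_count(self):
        ev = sample_evaluation_points(2, 2000, seed=0)
        assert ev.points.shape == (2000, 2)
        assert ev.points.min() >= -1 and ev.points.max() <= 1

    def test_uniform_moments(self):
        M = 5000
        ev = sample_evaluation_points(3, M, seed=1)
        se = np.sqrt(1.0 / 3.0 / M)  # var of U(-1,1) is 1/3
        assert np.all(np.abs(ev.points.mean(0)) < 3 * se)

    def test_seeded_determinism(self):
        a = sample_evaluation_points(2, 100, seed=9)
        b = sample_evaluation_points(2, 100, seed=9)
        assert np.array_equal(a.points, b.points)


class TestActivities:
    def test_nonnegative_everywhere(self):
        K = draw_encoders("unit_sphere_rows", 50, 2, seed=0)
        tun = calibrate_gain_bias(50, seed=0)
        ev = sample_evaluation_points(2, 200, seed=0)
        A = estimate_activities(tun, K, ev)
        assert A.shape == (200, 50)
        assert np.all(A >= 0)

    def test_matches_spiking_simulation(self):
        # the rate estimate must agree with filtered traces from a real
        # spiking run at a held latent value (u / tau_syn estimates rate)
        K = draw_encoders("unit_sphere_rows", 12, 2, seed=2)
        tun = calibrate_gain_bias(12, seed=2)
        rng = np.random.default_rng(0)
        tau = 0.02
        for trial in range(5):
            x = rng.uniform(-1, 1, 2)
            drive = tun.gains * (K.entries @ x) + tun.biases
            expected = lif_rate(drive, NEF_LIF)
            raster, traces = simulate_lif(lambda t, d=drive: d, NEF_LIF,
                                          3.0, 1e-4, tau_syn=tau)
            measured = traces.u[:, int(0.5 / 1e-4):].mean(axis=1) / tau
            active = expected > 20
            assert np.all(np.abs(measured[active] - expected[active])
                          / expected[active] < 0.1)


class TestSolveDecoders:
    def test_zero_targets_give_zero_decoders(self):
        A = np.random.default_rng(0).random((50, 5)) * 100
        Phi = solve_decoders(A, np.zeros((50, 1)))
        assert np.allclose(Phi, 0.0)

    def test_scalar_regression_recovers_constant(self):
        a = np.linspace(1, 100, 60)[:, None]
        Phi = solve_decoders(a, 0.5 * a[:, 0][:, None], ridge=1e-9)
        assert Phi[0, 0] == pytest.approx(0.5, rel=1e-4)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        A = rng.random((5, 3)) * 50
        X = rng.standard_normal((5, 2))
        ridge = 0.01
        Phi = solve_decoders(A, X, ridge)
        sigma = ridge * np.abs(A).max()
        closed = np.linalg.solve(A.T @ A + 5 * sigma**2 * np.eye(3),
                                 A.T @ X).T
        assert np.allclose(Phi, closed, atol=1e-10)

    def test_rank_deficiency_requires_ridge(self):
        A = np.ones((10, 3))
        with pytest.raises(np.linalg.LinAlgError):
            solve_decoders(A, np.ones((10, 1)), ridge=0.0)


class TestDynamicsTransform:
    def test_integrator_limit(self):
        Phi = np.random.default_rng(4).standard_normal((2, 30))
        assert np.array_equal(dynamics_transform(np.zeros((2, 2)), Phi,
                                                 0.01), Phi)

    def test_scaling_identity(self):
        Phi = np.random.default_rng(5).standard_normal((2, 10))
        G = dynamics_transform(np.eye(2) / 0.01, Phi, 0.01)
        assert np.allclose(G, 2 * Phi)

    def test_oscillator_relative_norm(self):
        # ||Gamma - Phi|| / ||Phi|| = ||tau A||_2 = 2 pi f tau
        Phi = np.linalg.qr(
            np.random.default_rng(6).standard_normal((30, 2)))[0].T
        tau, f = 0.01, 2.0
        A = oscillator_matrix(2 * np.pi * f)
        G = dynamics_transform(A, Phi, tau)
        assert np.linalg.norm(G - Phi) / np.linalg.norm(Phi) == \
            pytest.approx(2 * np.pi * f * tau, rel=1e-10)


class TestAssembleWeights:
    def test_rank_bounded_by_latent_dimension(self):
        rng = np.random.default_rng(7)
        K = draw_encoders("unit_sphere_rows", 40, 3, seed=0)
        Phi = rng.standard_normal((3, 40))
        W = assemble_weights(K, Phi, rng.random(40) + 1)
        s = np.linalg.svd(W, compute_uv=False)
        assert np.sum(s > s[0] * 1e-12) <= 3

    def test_matches_factored_application(self):
        rng = np.random.default_rng(8)
        K = draw_encoders("unit_sphere_rows", 25, 2, seed=1)
        Phi = rng.standard_normal((2, 25))
        g = rng.random(25) + 0.5
        W = assemble_weights(K, Phi, g)
        u = rng.standard_normal(25)
        assert np.allclose(W @ u, g * (K.entries @ (Phi @ u)), atol=1e-12)


class TestClosedLoop:
    def test_network_retains_clamped_values(self):
        net = build_nef_network(400, 2, seed=0)
        target = make_step_targets(2, duration=1.5, dt=1e-3, period=0.5,
                                   fix_len=0.1, seed=4)
        _, decoded = nef_simulate(net, target, seed=0)
        errs = []
        for p in range(3):
            i0, i1 = int((p * 0.5 + 0.15) * 1000), int((p + 1) * 0.5 * 1000)
            errs.append(np.abs(decoded.values[:, i0:i1]
                               - target.values[:, i0:i1]).mean())
        assert np.mean(errs) < 0.15

    def test_relearning_keeps_tuning_but_refits_decoders(self):
        net = build_nef_network(200, 2, seed=1)
        new = relearn_nef(net, net.K, relearn_seed=12345)
        assert new.tuning is net.tuning
        assert not np.array_equal(new.Phi, net.Phi)
        # fresh evaluation points barely change the solution
        corr = np.corrcoef(new.Phi.ravel(), net.Phi.ravel())[0, 1]
        assert corr > 0.98
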