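"""Synthetic target generators: protocols, encoders, latent dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from manifold_perturb.targets import (
    EncoderScheme,
    LatentTrajectory,
    draw_encoders,
    double_oscillator_field,
    limit_cycle_reference,
    make_oscillator_targets,
    make_step_targets,
    oscillator_matrix,
)


class TestStepTargets:
    def test_periodic_fixation_windows(self):
        t = make_step_targets(2, duration=2.5, dt=1e-3, period=0.5,
                              fix_len=0.1, seed=0)
        # five fixation windows of 100 ms each
        edges = np.flatnonzero(np.diff(t.fixation_mask.astype(int)) == 1)
        assert t.fixation_mask[0]
        assert 1 + edges.size == 5
        lengths = []
        in_fix = np.flatnonzero(t.fixation_mask)
        breaks = np.split(in_fix, np.flatnonzero(np.diff(in_fix) > 1) + 1)
        assert len(breaks) == 5
        for b in breaks:
            assert b.size == pytest.approx(100, abs=1)

    def test_value_held_between_fixations(self):
        t = make_step_targets(3, duration=1.0, dt=1e-3, period=0.5,
                              fix_len=0.1, value_range=(-2, 2), seed=5)
        # within each period the target is constant at the clamped value
        first = t.values[:, :500]
        assert np.all(first == first[:, :1])
        assert np.all(np.abs(t.values) <= 2)

    def test_full_period_clamp_is_degenerate(self):
        t = make_step_targets(2, duration=1.0, dt=1e-3, period=0.5,
                              fix_len=0.5, seed=0)
        assert t.fixation_mask.all()

    def test_seeded_determinism(self):
        a = make_step_targets(2, duration=1.0, dt=1e-3, seed=7)
        b = make_step_targets(2, duration=1.0, dt=1e-3, seed=7)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.fixation_mask, b.fixation_mask)

    @pytest.mark.parametrize("kwargs", [
        dict(duration=-1.0), dict(dt=-1e-3), dict(period=0.3),
        dict(fix_len=0.6),
    ])
    def test_invalid_arguments(self, kwargs):
        base = dict(D=2, duration=1.0, dt=1e-3, period=0.5, fix_len=0.1)
        base.update(kwargs)
        with pytest.raises(ValueError):
            make_step_targets(**base)


class TestOscillatorTargets:
    def test_zero_frequency_is_constant(self):
        t = make_oscillator_targets(0.0, 1.0, 1e-3, amplitude=2.0)
        assert np.allclose(t.values[0], 2.0)
        assert np.allclose(t.values[1], 0.0)

    def test_two_full_cycles(self):
        t = make_oscillator_targets(2.0, 1.0, 1e-4)
        x1 = t.values[0]
        # cos(4 pi t) has 4 falling+rising zero crossings over 1 s
        crossings = np.sum(np.diff(np.sign(x1)) != 0)
        assert crossings == 4
        assert x1[0] == pytest.approx(1.0)

    def test_satisfies_linear_ode(self):
        f, dt, amp = 3.0, 1e-4, 1.5
        t = make_oscillator_targets(f, 0.5, dt, amplitude=amp)
        A = oscillator_matrix(2 * np.pi * f)
        xdot = np.gradient(t.values, dt, axis=1)
        resid = np.linalg.norm(xdot - A @ t.values, axis=0)
        assert resid.max() < 10 * dt * amp * (2 * np.pi * f) ** 2


class TestEncoders:
    def test_unit_sphere_rows_normalized(self):
        K = draw_encoders(EncoderScheme.unit_sphere_rows, 200, 3, seed=1)
        assert np.allclose(np.linalg.norm(K.entries, axis=1), 1.0,
                           atol=1e-12)

    def test_uniform_box_bounds_and_moments(self):
        K = draw_encoders("uniform_box", 4000, 2, scale=100.0, seed=2)
        assert np.abs(K.entries).max() <= 100.0
        # column variance of U(-s, s) is s^2 / 3
        var = K.entries.var(axis=0)
        se = 100.0**2 / 3 * np.sqrt(2 / 4000) * 3
        assert np.all(np.abs(var - 100.0**2 / 3) < 3 * se)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            draw_encoders("custom", 10, 2)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_seeded_determinism(self, seed):
        a = draw_encoders("unit_sphere_rows", 50, 2, seed=seed)
        b = draw_encoders("unit_sphere_rows", 50, 2, seed=seed)
        assert np.array_equal(a.entries, b.entries)


class TestDoubleOscillator:
    def test_origin_is_fixed_point(self):
        assert np.allclose(double_oscillator_field(np.zeros(4)), 0.0)

    def test_field_tangential_on_cycle(self):
        x = np.array([1.0, 0.0, 0.0, 1.0])
        f = double_oscillator_field(x, omega=2 * np.pi, alpha=0.3)
        # radial terms vanish at unit amplitude: f is a pure rotation
        assert f[0] == pytest.approx(0.0, abs=1e-12)
        assert f[3] == pytest.approx(0.0, abs=1e-12)

    def test_cycle_radius_preserved(self):
        traj = limit_cycle_reference(2 * np.pi * 2, 0.2,
                                     np.array([1.0, 0, 1.0, 0]),
                                     duration=1.0, dt=1e-3)
        r1 = np.hypot(traj.values[0], traj.values[1])
        r2 = np.hypot(traj.values[2], traj.values[3])
        assert np.allclose(r1, 1.0, atol=1e-4)
        assert np.allclose(r2, 1.0, atol=1e-4)

    def test_origin_stays_fixed(self):
        traj = limit_cycle_reference(2 * np.pi * 2, 0.2, np.zeros(4),
                                     duration=0.2, dt=1e-3)
        assert np.allclose(traj.values, 0.0)

    def test_amplitude_converges_from_inside(self):
        # radial ODE oracle: dr/dt = a r (1 - r^2) from r0 solves to
        # r(t)^2 = r0^2 e^{2at} / (1 - r0^2 + r0^2 e^{2at})
        # time to reach 1% of the cycle: t = ln(49.25 * 3) / (2 alpha) ~ 12.5 s
        alpha, r0 = 0.2, 0.5
        T = 14.0
        e = np.exp(2 * alpha * T)
        r_expect = np.sqrt(r0**2 * e / (1 - r0**2 + r0**2 * e))
        traj = limit_cycle_reference(2 * np.pi * 2, alpha,
                                     np.array([r0, 0, r0, 0]), T + 0.01,
                                     dt=1e-3)
        i = int(T / 1e-3)
        r1 = np.hypot(traj.values[0, i], traj.values[1, i])
        assert r1 == pytest.approx(r_expect, rel=1e-3)
        assert abs(r1 - 1.0) < 0.01

    def test_amplitude_attracts_from_multiple_starts(self):
        for x0 in ([0.3, 0, 1.5, 0], [0.1, 0.1, 0.2, -0.2]):
            traj = limit_cycle_reference(2 * np.pi * 2, 0.2,
                                         np.array(x0, float), 25.0, 1e-3)
            end = traj.values[:, -1]
            assert np.hypot(end[0], end[1]) == pytest.approx(1.0, abs=0.02)
            assert np.hypot(end[2], end[3]) == pytest.approx(1.0, abs=0.02)


class TestSerialization:
    def test_txt_roundtrip(self, tmp_path):
        t = make_step_targets(2, duration=1.0, dt=1e-3, seed=3)
        p = tmp_path / "traj.tsv"
        t.to_txt(p)
        back = LatentTrajectory.from_txt(p)
        assert np.allclose(back.values, t.values)
        assert np.array_equal(back.fixation_mask, t.fixation_mask)

    def test_npz_roundtrip(self, tmp_path):
        t = make_oscillator_targets(1.0, 0.5, 1e-3)
        p = tmp_path / "traj.npz"
        t.to_npz(p)
        back = LatentTrajectory.from_npz(p)
        assert np.array_equal(back.values, t.values)
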