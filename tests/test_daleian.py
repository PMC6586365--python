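"""Sign-constrained weight optimization: masks, row solves, statistics."""

import itertools

import numpy as np
import pytest

from manifold_perturb.daleian import (
    ConstrainedWeights,
    make_constraint_mask,
    oscillator_field,
    solve_constrained_row,
    solve_constrained_weights,
    weight_statistics,
)
from manifold_perturb.nef import calibrate_gain_bias, sample_evaluation_points
from manifold_perturb.targets import draw_encoders


class TestConstraintMask:
    def test_full_sparsity_empties_mask(self):
        C = make_constraint_mask(50, xi=1.0, seed=0)
        assert np.all(C.C == 0)

    def test_sign_structure_by_presynaptic_column(self):
        C = make_constraint_mask(100, xi=0.5, eps_frac=0.8, seed=1)
        n_exc = 80
        assert np.all(C.C[:, :n_exc] >= 0)
        assert np.all(C.C[:, n_exc:] <= 0)

    def test_zero_fraction_within_binomial_interval(self):
        N, xi = 200, 0.75
        C = make_constraint_mask(N, xi=xi, seed=2)
        frac = (C.C == 0).mean()
        se = np.sqrt(xi * (1 - xi)) / N  # N^2 Bernoulli draws
        assert abs(frac - xi) < 4 * se

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_constraint_mask(10, xi=1.5)
        with pytest.raises(ValueError):
            make_constraint_mask(10, eps_frac=0.0)


def _brute_force_row(design, target, signs):
    """Exhaustive active-set search over sign-feasible supports."""
    allowed = np.flatnonzero(signs != 0)
    best, best_obj = np.zeros(signs.size), np.inf
    for r in range(len(allowed) + 1):
        for subset in itertools.combinations(allowed, r):
            w = np.zeros(signs.size)
            if subset:
                sub = list(subset)
                sol, *_ = np.linalg.lstsq(design[:, sub], target,
                                          rcond=None)
                if np.any(np.sign(sol) * signs[sub] < 0):
                    continue
                w[sub] = sol
            obj = np.sum((target - design @ w) ** 2)
            if obj < best_obj - 1e-12:
                best, best_obj = w, obj
    return best


class TestConstrainedRowSolve:
    def test_matches_brute_force_active_set(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            design = rng.standard_normal((30, 3))
            target = rng.standard_normal(30)
            signs = rng.choice([-1, 0, 1], size=3)
            w = solve_constrained_row(design, target, signs)
            w_ref = _brute_force_row(design, target, signs)
            assert np.sum((target - design @ w) ** 2) == pytest.approx(
                np.sum((target - design @ w_ref) ** 2), abs=1e-9)

    def test_unconstrained_solution_reached_when_feasible(self):
        rng = np.random.default_rng(4)
        design = rng.random((40, 3)) + 0.1
        w_true = np.array([0.5, 1.2, 0.3])
        target = design @ w_true
        w = solve_constrained_row(design, target, np.ones(3, dtype=int))
        assert np.allclose(w, w_true, atol=1e-8)

    def test_masked_entries_exactly_zero(self):
        rng = np.random.default_rng(5)
        design = rng.standard_normal((20, 4))
        signs = np.array([1, 0, -1, 0])
        w = solve_constrained_row(design, rng.standard_normal(20), signs)
        assert w[1] == 0.0 and w[3] == 0.0
        assert w[0] >= 0.0 and w[2] <= 0.0


class TestOscillatorField:
    def test_zero_fixed_point(self):
        assert np.allclose(oscillator_field(np.zeros(4)), 0.0)

    def test_tangential_on_unit_cycles(self):
        x = np.array([0.0, 1.0, 1.0, 0.0])
        f = oscillator_field(x, omega=4 * np.pi, alpha=0.2)
        # no radial component on the attracting cycle
        assert x[:2] @ f[:2] == pytest.approx(0.0, abs=1e-12)
        assert x[2:] @ f[2:] == pytest.approx(0.0, abs=1e-12)

    def test_radial_eigenvalue_at_cycle(self):
        # d/dr [alpha r (1 - r^2)] at r = 1 equals -2 alpha
        alpha, eps = 0.2, 1e-6
        def radial(r):
            return alpha * r * (1 - r**2)
        deriv = (radial(1 + eps) - radial(1 - eps)) / (2 * eps)
        assert deriv == pytest.approx(-2 * alpha, rel=1e-6)

    def test_frequency_doubling_between_pairs(self):
        x = np.array([1.0, 0.0, 1.0, 0.0])
        f = oscillator_field(x, omega=2 * np.pi, alpha=0.0)
        assert f[3] == pytest.approx(2 * f[1])


class TestSolveConstrainedWeights:
    def _small_problem(self, N=40, M=300, seed=0):
        rng = np.random.default_rng(seed)
        K = draw_encoders("unit_sphere_rows", N, 4, seed=seed)
        tuning = calibrate_gain_bias(N, seed=seed)
        ev = sample_evaluation_points(4, M, (-1.2, 1.2), seed=seed)
        C = make_constraint_mask(N, xi=0.5, eps_frac=0.8, seed=seed)
        return K, tuning, ev, C

    def test_sign_constraints_honored_everywhere(self):
        K, tuning, ev, C = self._small_problem()
        cw = solve_constrained_weights(K, tuning, oscillator_field, ev, C,
                                       0.01)
        assert np.all(cw.W[C.C == 0] == 0)
        assert np.all(cw.W[C.C == 1] >= 0)
        assert np.all(cw.W[C.C == -1] <= 0)

    def test_row_solves_independent_of_order(self):
        K, tuning, ev, C = self._small_problem(seed=1)
        a = solve_constrained_weights(K, tuning, oscillator_field, ev, C,
                                      0.01)
        b = solve_constrained_weights(K, tuning, oscillator_field, ev, C,
                                      0.01)
        assert np.array_equal(a.W, b.W)


class TestWeightStatistics:
    def test_empty_weights(self):
        C = make_constraint_mask(20, xi=0.5, seed=6)
        cw = ConstrainedWeights(np.zeros((20, 20)), C, np.zeros(20))
        stats = weight_statistics(cw)
        assert stats["connection_probability_exc"] == 0.0
        assert stats["connection_probability_inh"] == 0.0

    def test_connection_probability_counts_nonzeros(self):
        C = make_constraint_mask(10, xi=0.0, eps_frac=0.8, seed=7)
        W = np.zeros((10, 10))
        W[0, 0] = 1.0
        W[0, 9] = -2.0
        cw = ConstrainedWeights(W, C, np.zeros(10))
        stats = weight_statistics(cw)
        assert stats["connection_probability_exc"] == pytest.approx(1 / 80)
        assert stats["connection_probability_inh"] == pytest.approx(1 / 20)

    def test_kurtosis_conventions_differ_by_three(self):
        rng = np.random.default_rng(8)
        C = make_constraint_mask(30, xi=0.0, eps_frac=0.5, seed=8)
        W = np.abs(rng.lognormal(0, 1, (30, 30)))
        W[:, 15:] *= -1
        cw = ConstrainedWeights(W, C, np.zeros(30))
        stats = weight_statistics(cw)
        assert stats["log_weight_kurtosis_pearson"] == pytest.approx(
            stats["log_weight_kurtosis_excess"] + 3.0)
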