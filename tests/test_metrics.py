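"""Mode extraction and similarity measures."""

import numpy as np
import pytest

from manifold_perturb.metrics import (
    columnwise_similarity,
    fa_modes,
    pca_modes,
    subsample_neurons,
    subspace_cosine,
    weight_similarity,
    zero_crossing_frequency,
)
from manifold_perturb.spiking import BinnedRates


def _counts_from_loadings(L, T, noise, seed, diag=None):
    rng = np.random.default_rng(seed)
    N, D = L.shape
    z = rng.standard_normal((D, T))
    X = L @ z
    if diag is None:
        X = X + noise * rng.standard_normal((N, T))
    else:
        X = X + diag[:, None] * rng.standard_normal((N, T))
    X = np.round(X - X.min() + 1).astype(int)
    return BinnedRates(X, 0.05)


class TestPCAModes:
    def test_rank_one_data_fully_explained(self):
        v = np.arange(1, 7, dtype=float)
        counts = np.outer(v, np.array([1, 3, 2, 5, 4])).astype(int)
        modes = pca_modes(BinnedRates(counts, 0.05), 1)
        assert modes.variance_explained[0] == pytest.approx(1.0)

    def test_components_orthonormal(self):
        rng = np.random.default_rng(0)
        rates = BinnedRates(rng.poisson(3.0, (30, 25)), 0.05)
        modes = pca_modes(rates, 3)
        assert np.allclose(modes.columns.T @ modes.columns, np.eye(3),
                           atol=1e-10)

    def test_matches_covariance_eigenvectors(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(4.0, (4, 10))
        modes = pca_modes(BinnedRates(counts, 0.05), 2)
        X = counts.T - counts.T.mean(0)
        w, v = np.linalg.eigh(X.T @ X)
        top = v[:, ::-1][:, :2]
        # same subspace up to sign/order
        assert subspace_cosine(modes.columns, top) == pytest.approx(1.0)

    def test_needs_enough_bins(self):
        with pytest.raises(ValueError):
            pca_modes(BinnedRates(np.ones((5, 2), int), 0.05), 2)


class TestFAModes:
    def test_recovers_generative_loadings(self):
        rng = np.random.default_rng(2)
        L = rng.standard_normal((120, 2)) * 3
        rates = _counts_from_loadings(L, 300, 0.5, seed=3)
        modes = fa_modes(rates, 2)
        assert subspace_cosine(modes.columns, L) > 0.95

    def test_isotropic_noise_matches_pca(self):
        rng = np.random.default_rng(4)
        L = rng.standard_normal((80, 2)) * 2
        rates = _counts_from_loadings(L, 400, 1.0, seed=5)
        fa = fa_modes(rates, 2)
        pca = pca_modes(rates, 2)
        assert subspace_cosine(fa.columns, pca.columns) > 0.95


class TestSubspaceCosine:
    def test_identical_subspace(self):
        A = np.random.default_rng(0).standard_normal((40, 3))
        assert subspace_cosine(A, A) == pytest.approx(1.0)

    def test_orthogonal_subspaces(self):
        A = np.eye(6)[:, :2]
        B = np.eye(6)[:, 3:5]
        assert subspace_cosine(A, B) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_column_recombination(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((50, 3))
        B = rng.standard_normal((50, 3))
        M = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        assert subspace_cosine(A @ M, B) == pytest.approx(
            subspace_cosine(A, B), abs=1e-10)

    def test_rank_deficient_rejected(self):
        A = np.ones((10, 2))
        with pytest.raises(np.linalg.LinAlgError):
            subspace_cosine(A, np.eye(10)[:, :2])


class TestColumnwiseSimilarity:
    def test_self_and_negated(self):
        A = np.random.default_rng(7).standard_normal((100, 2))
        assert columnwise_similarity(A, A) == pytest.approx(1.0)
        assert columnwise_similarity(A, -A) == pytest.approx(1.0)

    def test_detects_within_manifold_swap(self):
        # swapping near-orthogonal random columns looks identical to
        # subspace_cosine but drives the column correlation to ~0
        A = np.random.default_rng(8).standard_normal((3000, 2))
        B = A[:, ::-1]
        assert subspace_cosine(A, B) == pytest.approx(1.0)
        assert columnwise_similarity(A, B) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            columnwise_similarity(np.ones((10, 1)), np.ones((10, 1)))


class TestWeightSimilarity:
    def test_identical_matrices(self):
        W = np.random.default_rng(9).standard_normal((20, 20))
        rep = weight_similarity(W, W)
        assert rep.pearson_elementwise == pytest.approx(1.0)
        assert rep.frobenius_diff == 0.0

    def test_correlation_blind_to_scaling(self):
        W = np.random.default_rng(10).standard_normal((20, 20))
        rep = weight_similarity(W, 2 * W)
        assert rep.pearson_elementwise == pytest.approx(1.0)
        assert rep.frobenius_diff == pytest.approx(np.linalg.norm(W))

    def test_independent_matrices_uncorrelated(self):
        rng = np.random.default_rng(11)
        N = 100
        rep = weight_similarity(rng.standard_normal((N, N)),
                                rng.standard_normal((N, N)))
        assert abs(rep.pearson_elementwise) < 3.0 / N


class TestSubsampleNeurons:
    def test_full_sample_is_permutation(self):
        rng = np.random.default_rng(12)
        rates = BinnedRates(rng.poisson(2.0, (30, 10)), 0.05)
        sub = subsample_neurons(rates, 30, seed=0)
        assert sorted(map(tuple, sub.counts)) == sorted(map(tuple,
                                                            rates.counts))

    def test_dimensionality_preserved_under_subsampling(self):
        rng = np.random.default_rng(13)
        L = rng.standard_normal((200, 2)) * 4
        rates = _counts_from_loadings(L, 100, 0.5, seed=14)
        full = pca_modes(rates, 2).variance_explained
        half = pca_modes(subsample_neurons(rates, 100, seed=1), 2) \
            .variance_explained
        assert full[:2].sum() > 0.8
        assert half[:2].sum() > 0.8
        assert np.allclose(full[:2], half[:2], atol=0.1)

    def test_oversampling_rejected(self):
        rates = BinnedRates(np.ones((5, 4), int), 0.05)
        with pytest.raises(ValueError):
            subsample_neurons(rates, 6)


class TestZeroCrossingFrequency:
    @pytest.mark.parametrize("f", [1.0, 2.0, 4.0])
    def test_pure_sine(self, f):
        dt = 1e-3
        t = np.arange(0, 5, dt)
        x = np.sin(2 * np.pi * f * t)
        assert zero_crossing_frequency(x, dt, smooth_s=0.02) == \
            pytest.approx(f, rel=0.05)
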