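"""Neural-mode extraction and similarity measures.

Neural modes are the principal components (or factor loadings) of the
50 ms-binned spike-count matrix.  Subspace similarity is the cosine of
the mean principal angle between column spaces (1 = same subspace,
0 = orthogonal); within-manifold changes that preserve the subspace
are instead detected by the mean absolute column-wise correlation.
Weight matrices are compared element-wise (Pearson over all N^2
entries) and by the Frobenius norm of the difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import subspace_angles
from scipy.stats import pearsonr
from sklearn.decomposition import PCA, FactorAnalysis

from .spiking import BinnedRates


@dataclass(frozen=True)
class ModeMatrix:
    """An N x D basis of neural modes plus the PCA variance spectrum."""

    columns: np.ndarray
    variance_explained: Optional[np.ndarray] = None
    method: str = "pca"

    @property
    def N(self) -> int:
        return int(self.columns.shape[0])

    @property
    def D(self) -> int:
        return int(self.columns.shape[1])


@dataclass(frozen=True)
class SimilarityReport:
    """Similarity measures between two matrices (weights or modes)."""

    pearson_elementwise: Optional[float] = None
    frobenius_diff: Optional[float] = None
    subspace_cosine: Optional[float] = None
    columnwise_similarity: Optional[float] = None


def pca_modes(rates: BinnedRates, D: int) -> ModeMatrix:
    """Top-D principal components of the centered bins x neurons matrix.

    Centering subtracts each neuron's mean count over bins; counts are
    not variance-scaled (they share units).  The full
    variance-explained spectrum is attached.
    """
    X = rates.counts.T.astype(float)  # bins x neurons
    if X.shape[0] < D + 1:
        raise ValueError("need at least D + 1 bins for PCA")
    pca = PCA(n_components=min(X.shape))
    pca.fit(X)
    return ModeMatrix(pca.components_[:D].T, pca.explained_variance_ratio_,
                      "pca")


def fa_modes(rates: BinnedRates, D: int, tol: float = 1e-3,
             max_iter: int = 1000) -> ModeMatrix:
    """D-factor maximum-likelihood factor analysis loading matrix.

    Unlike PCA, factor analysis allows independent per-neuron noise
    variances, which is how manifold dimensionality is estimated from
    electrophysiological recordings.
    """
    X = rates.counts.T.astype(float)
    if X.shape[0] < D + 1:
        raise ValueError("need at least D + 1 bins for factor analysis")
    fa = FactorAnalysis(n_components=D, tol=tol, max_iter=max_iter)
    fa.fit(X)
    if fa.n_iter_ >= max_iter:
        raise RuntimeError(
            f"factor analysis did not converge in {fa.n_iter_} iterations")
    return ModeMatrix(fa.components_.T, None, "fa")


def subspace_cosine(A: np.ndarray, B: np.ndarray) -> float:
    """Cosine of the mean principal angle between the column spaces.

    Invariant to any invertible recombination of columns within either
    matrix; ranges from 0 (orthogonal subspaces) to 1 (equal).
    """
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    for M, name in ((A, "A"), (B, "B")):
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise np.linalg.LinAlgError(f"{name} is column-rank deficient")
    angles = subspace_angles(A, B)
    return float(np.cos(np.mean(angles)))


def columnwise_similarity(A: np.ndarray, B: np.ndarray) -> float:
    """Mean over columns of |Pearson correlation| between paired columns.

    Unlike :func:`subspace_cosine`, this detects within-manifold
    rearrangements: swapping two near-orthogonal columns drives it to
    zero while leaving the spanned subspace untouched.
    """
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    if A.shape != B.shape:
        raise ValueError("matched shapes required")
    sims = []
    for a, b in zip(A.T, B.T):
        if np.std(a) == 0 or np.std(b) == 0:
            raise ValueError("zero-variance column")
        sims.append(abs(pearsonr(a, b)[0]))
    return float(np.mean(sims))


def weight_similarity(W_old: np.ndarray, W_new: np.ndarray) -> SimilarityReport:
    """Element-wise Pearson correlation and Frobenius norm of difference.

    The correlation is over all N^2 entries (diagonal included) and is
    blind to global scaling; the Frobenius distance is not, which is
    why both are reported.
    """
    W_old = np.asarray(W_old, float)
    W_new = np.asarray(W_new, float)
    if W_old.shape != W_new.shape:
        raise ValueError("matched shapes required")
    a, b = W_old.ravel(), W_new.ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        r = 1.0 if np.allclose(a, b) else 0.0
    else:
        r = float(pearsonr(a, b)[0])
    return SimilarityReport(
        pearson_elementwise=r,
        frobenius_diff=float(np.linalg.norm(W_old - W_new)),
    )


def subsample_neurons(rates: BinnedRates, m: int, seed: int = 0) -> BinnedRates:
    """Binned counts of a uniform random subset of m neurons."""
    if m > rates.N:
        raise ValueError("cannot sample more neurons than available")
    rng = np.random.default_rng(seed)
    rows = rng.choice(rates.N, size=m, replace=False)
    return BinnedRates(rates.counts[rows], rates.bin_width)


def zero_crossing_frequency(trace: np.ndarray, dt: float,
                            smooth_s: float = 0.05) -> float:
    """Oscillation frequency from mean-crossings of a smoothed trace.

    The trace is boxcar-smoothed over ``smooth_s`` seconds, its mean
    removed, and the frequency estimated from the mean interval
    between sign changes (a half period), which is insensitive to
    partial periods at the edges.
    """
    x = np.asarray(trace, float)
    w = max(int(round(smooth_s / dt)), 1)
    if w > 1:
        kernel = np.ones(w) / w
        x = np.convolve(x, kernel, mode="valid")
    x = x - x.mean()
    nz = np.flatnonzero(x != 0)
    signs = np.sign(x[nz])
    change = np.flatnonzero(signs[1:] != signs[:-1])
    if change.size < 2:
        return 0.0
    crossings = nz[change + 1]
    half_period = np.mean(np.diff(crossings)) * dt
    return 1.0 / (2.0 * half_period)
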