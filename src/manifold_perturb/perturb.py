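"""Inside- and outside-manifold perturbations of the encoders.

An inside-manifold perturbation right-multiplies the encoders by a
D x D matrix Q (the spanned subspace is preserved when Q is
invertible; orthogonal Q additionally preserves geometry).  An
outside-manifold perturbation left-multiplies by an N x N row
permutation, which moves the neural modes out of the original
subspace.  After a perturbation the framework's learning / solve
procedure is re-run from scratch with the new encoders and identical
hyperparameters and targets, and the old and new feedback weight
matrices W = K Phi are compared (the static reservoir, and for
efficient coding the fast weights, are excluded).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

import numpy as np

from .targets import EncoderMatrix, EncoderScheme


class PerturbationKind(str, Enum):
    identity = "identity"
    inside_permutation = "inside_permutation"
    inside_rot45 = "inside_rot45"
    inside_gaussian = "inside_gaussian"
    inside_same_element = "inside_same_element"
    outside_block_swap = "outside_block_swap"
    outside_permutation = "outside_permutation"
    redraw_K = "redraw_K"


INSIDE_KINDS = {
    PerturbationKind.inside_permutation,
    PerturbationKind.inside_rot45,
    PerturbationKind.inside_gaussian,
    PerturbationKind.inside_same_element,
}
OUTSIDE_KINDS = {
    PerturbationKind.outside_block_swap,
    PerturbationKind.outside_permutation,
}
#: inside perturbations whose Q is orthogonal (exact weight invariance
#: in the ideal, rank-D case)
ORTHOGONAL_INSIDE = {
    PerturbationKind.inside_permutation,
    PerturbationKind.inside_rot45,
}


@dataclass(frozen=True)
class PerturbationSpec:
    """A perturbation: its kind, the transform Q, and a seed."""

    kind: PerturbationKind
    Q: Optional[np.ndarray]
    seed: int = 0


def make_inside_Q(kind: Union[PerturbationKind, str], D: int,
                  seed: int = 0) -> np.ndarray:
    """Construct the D x D inside-manifold transform for ``kind``."""
    kind = PerturbationKind(kind)
    if D < 2:
        raise ValueError("inside perturbations require D >= 2")
    rng = np.random.default_rng(seed)
    if kind == PerturbationKind.inside_permutation:
        if D == 2:
            return np.array([[0.0, 1.0], [1.0, 0.0]])
        perm = np.arange(D)
        while np.all(perm == np.arange(D)):
            perm = rng.permutation(D)
        return permutation_matrix(perm)
    if kind == PerturbationKind.inside_rot45:
        Q = np.eye(D)
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        Q[0, 0], Q[0, 1], Q[1, 0], Q[1, 1] = c, -s, s, c
        return Q
    if kind == PerturbationKind.inside_gaussian:
        return rng.standard_normal((D, D))
    if kind == PerturbationKind.inside_same_element:
        return np.full((D, D), rng.standard_normal())
    raise ValueError(f"{kind} is not an inside perturbation")


def permutation_matrix(perm: np.ndarray) -> np.ndarray:
    """Matrix P with P[i, perm[i]] = 1, so (P x)_i = x_perm[i]."""
    perm = np.asarray(perm, dtype=int)
    P = np.zeros((perm.size, perm.size))
    P[np.arange(perm.size), perm] = 1.0
    return P


def make_outside_Q(kind: Union[PerturbationKind, str], N: int, seed: int = 0,
                   n_blocks: int = 2,
                   block_perm: Optional[np.ndarray] = None) -> np.ndarray:
    """Construct the N x N outside-manifold row permutation.

    ``outside_block_swap`` exchanges the first and last N/2 rows.
    ``outside_permutation`` permutes ``n_blocks`` equal row blocks
    according to ``block_perm`` (random non-identity if omitted).
    """
    kind = PerturbationKind(kind)
    if kind == PerturbationKind.outside_block_swap:
        if N % 2:
            raise ValueError("block swap requires even N")
        n_blocks, block_perm = 2, np.array([1, 0])
    elif kind != PerturbationKind.outside_permutation:
        raise ValueError(f"{kind} is not an outside perturbation")
    if N % n_blocks:
        raise ValueError("N must divide into equal blocks")
    if block_perm is None:
        rng = np.random.default_rng(seed)
        block_perm = np.arange(n_blocks)
        while np.all(block_perm == np.arange(n_blocks)):
            block_perm = rng.permutation(n_blocks)
    block_perm = np.asarray(block_perm, int)
    size = N // n_blocks
    row_perm = np.concatenate(
        [np.arange(size) + b * size for b in block_perm])
    return permutation_matrix(row_perm)


def enumerate_inside_permutations(D: int) -> list[np.ndarray]:
    """All D! - 1 non-identity D x D permutation matrices, in
    lexicographic order of the underlying permutation."""
    if D > 6:
        raise ValueError("factorial guard: D must be <= 6")
    mats = []
    for perm in itertools.permutations(range(D)):
        if perm == tuple(range(D)):
            continue
        mats.append(permutation_matrix(np.array(perm)))
    return mats


def make_perturbation(kind: Union[PerturbationKind, str], N: int, D: int,
                      seed: int = 0) -> PerturbationSpec:
    """Build the PerturbationSpec for any kind at the given sizes."""
    kind = PerturbationKind(kind)
    if kind == PerturbationKind.identity:
        return PerturbationSpec(kind, None, seed)
    if kind == PerturbationKind.redraw_K:
        return PerturbationSpec(kind, None, seed)
    if kind in INSIDE_KINDS:
        return PerturbationSpec(kind, make_inside_Q(kind, D, seed), seed)
    return PerturbationSpec(kind, make_outside_Q(kind, N, seed), seed)


def perturb_encoders(K: EncoderMatrix, spec: PerturbationSpec) -> EncoderMatrix:
    """Apply the perturbation: K Q (inside), Q K (outside) or a redraw."""
    if spec.kind == PerturbationKind.identity:
        return K
    if spec.kind == PerturbationKind.redraw_K:
        from .targets import draw_encoders

        scheme = K.draw_scheme
        if scheme == EncoderScheme.uniform_box:
            return draw_encoders(scheme, K.N, K.D,
                                 float(np.abs(K.entries).max()),
                                 seed=spec.seed)
        if scheme == EncoderScheme.unit_sphere_rows:
            return draw_encoders(scheme, K.N, K.D,
                                 float(np.linalg.norm(K.entries[0])),
                                 seed=spec.seed)
        # custom scheme: redraw i.i.d. normal entries matching the
        # original entry scale
        rng = np.random.default_rng(spec.seed)
        sigma = float(np.std(K.entries))
        return EncoderMatrix(sigma * rng.standard_normal(K.entries.shape))
    if spec.kind in INSIDE_KINDS:
        return EncoderMatrix(K.entries @ spec.Q, EncoderScheme.custom)
    return EncoderMatrix(spec.Q @ K.entries, EncoderScheme.custom)


def perturb_and_relearn(network, spec: PerturbationSpec, relearn_seed: int):
    """Perturb the encoders, re-run learning, return (W_old, W_new, net_new).

    ``network`` may be any framework network object exposing
    ``feedback_weights()``, its encoders ``K``, and a relearn entry
    point; dispatch happens on the concrete type.
    """
    from .daleian import DaleianNetwork, relearn_daleian
    from .ec import ECNetwork, build_ec_network
    from .force import ForceNetwork
    from .nef import NEFNetwork, relearn_nef

    K_new = perturb_encoders(network.K, spec)
    W_old = network.feedback_weights()
    if isinstance(network, NEFNetwork):
        net_new = relearn_nef(network, K_new, relearn_seed)
    elif isinstance(network, ECNetwork):
        net_new = build_ec_network(K_new, network.tau_syn, network.mu,
                                   network.nu, network.A_dyn,
                                   network.threshold_convention)
    elif isinstance(network, DaleianNetwork):
        net_new = relearn_daleian(network, K_new, relearn_seed)
    elif isinstance(network, ForceNetwork):
        raise TypeError(
            "FORCE relearning needs a training schedule; use "
            "force_train with the perturbed encoders (see experiments)")
    else:
        raise TypeError(f"unknown framework {type(network)!r}")
    return W_old, net_new.feedback_weights(), net_new
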