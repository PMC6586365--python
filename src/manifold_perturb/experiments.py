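"""Experiment runners reproducing the study's analyses at two scales.

Each runner builds networks, applies the study protocol and returns
plain dictionaries / DataFrames; the numbered scripts under
``analysis/`` and the command-line interface are thin wrappers around
these functions.  The ``desk`` profile targets single-CPU minutes by
shrinking the reservoir network and the constrained-solve problem
sizes; ``full`` keeps the original scales (the constrained solve at
N = 5000 with 40,000 evaluation points takes hours).
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import daleian as dal
from . import ec as ec_mod
from . import force as force_mod
from . import nef as nef_mod
from .metrics import (
    columnwise_similarity,
    fa_modes,
    pca_modes,
    subspace_cosine,
    weight_similarity,
    zero_crossing_frequency,
)
from .perturb import (
    PerturbationKind,
    make_perturbation,
    perturb_and_relearn,
    perturb_encoders,
    permutation_matrix,
)
from .spiking import bin_spikes
from .targets import (
    EncoderScheme,
    LatentTrajectory,
    draw_encoders,
    make_step_targets,
    oscillator_matrix,
)

FRAMEWORKS = ("force", "nef", "ec")
_FW_ID = {"force": 1, "nef": 2, "ec": 3}
_COND_ID = {"inside": 1, "outside": 2, "redraw": 3}
BIN_WIDTH = 0.05
PROTOCOL = dict(duration=2.5, period=0.5, fix_len=0.1)


@dataclass(frozen=True)
class Profile:
    """Problem sizes for one run; ``desk`` trades scale for minutes."""

    name: str = "desk"
    nef_N: int = 1000
    ec_N: int = 1000
    force_N: int = 300
    force_dt: float = 1e-4
    force_total_s: float = 25.0
    force_learn_s: float = 20.0
    sweep_force_N: int = 200
    sweep_force_total_s: float = 15.0
    sweep_force_learn_s: float = 12.5
    daleian_N: int = 500
    daleian_n_eval: int = 4000
    readout_duration_s: float = 2.5

    @classmethod
    def get(cls, name: str) -> "Profile":
        if name == "desk":
            return cls()
        if name == "full":
            return cls(name="full", force_N=1000, force_dt=5e-5,
                       force_total_s=50.0, force_learn_s=45.0,
                       sweep_force_N=1000, sweep_force_total_s=50.0,
                       sweep_force_learn_s=45.0, daleian_N=5000,
                       daleian_n_eval=40000, readout_duration_s=2.5)
        raise ValueError(f"unknown profile {name!r}")


def _spawn(seed: int, *key: int) -> int:
    """Derive a child seed below 2^31 from a base seed and a key path."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# framework construction helpers

def build_framework(framework: str, profile: Profile, seed: int,
                    A_dyn: Optional[np.ndarray] = None,
                    target: Optional[LatentTrajectory] = None):
    """Build (and where applicable train) one framework's D=2 network."""
    if framework == "nef":
        return nef_mod.build_nef_network(profile.nef_N, 2, seed=seed,
                                         A_dyn=A_dyn)
    if framework == "ec":
        K = ec_mod.draw_ec_encoders(profile.ec_N, 2, seed=_spawn(seed, 0))
        return ec_mod.build_ec_network(K, A_dyn=A_dyn)
    if framework == "force":
        if target is None:
            target = make_step_targets(2, seed=_spawn(seed, 1),
                                       dt=profile.force_dt, **PROTOCOL)
        K = draw_encoders(EncoderScheme.uniform_box, profile.force_N, 2,
                          scale=100.0, seed=_spawn(seed, 0))
        reservoir = force_mod.build_reservoir(profile.force_N,
                                              seed=_spawn(seed, 2))
        schedule = force_mod.TrainingSchedule(target, profile.force_total_s,
                                              profile.force_learn_s)
        # RLS update interval fixed at 0.5 ms of simulated time
        stride = max(1, round(5e-4 / profile.force_dt))
        return force_mod.force_train(K, reservoir, schedule,
                                     dt=profile.force_dt,
                                     seed=_spawn(seed, 3),
                                     update_stride=stride)
    raise ValueError(f"unknown framework {framework!r}")


def _simulate_protocol(framework: str, network, profile: Profile, seed: int):
    """Run the periodic-fixation protocol; return (raster, decoded)."""
    if framework == "nef":
        target = make_step_targets(2, dt=network.dt,
                                   seed=_spawn(seed, 10), **PROTOCOL)
        return nef_mod.nef_simulate(network, target, seed=_spawn(seed, 11))
    if framework == "ec":
        target = make_step_targets(2, dt=ec_mod.DEFAULT_DT,
                                   seed=_spawn(seed, 10), **PROTOCOL)
        raster, decoded = ec_mod.ec_simulate(
            network, target.scaled(ec_mod.LATENT_SCALE),
            seed=_spawn(seed, 11))
        return raster, decoded.scaled(1.0 / ec_mod.LATENT_SCALE)
    if framework == "force":
        # the reservoir is evaluated on the trained pattern (retention of
        # arbitrary unseen values is not part of the protocol)
        target = make_step_targets(2, dt=network.dt,
                                   seed=_spawn(seed, 1), **PROTOCOL)
        return force_mod.force_simulate(network, target,
                                        seed=_spawn(seed, 11))
    raise ValueError(framework)


# ---------------------------------------------------------------------------
# experiments

def run_mode_identification(framework: str, profile: str = "desk",
                            seed: int = 0) -> dict:
    """Build a D=2 network, run the fixation protocol, extract modes.

    Returns the decoded traces, the binned-count variance spectrum and
    the 4 x 4 generalized-correlation (subspace-cosine) matrix among
    the encoders K, the decoders Phi^T, the top-2 principal components
    and the 2-factor loading matrix.
    """
    prof = Profile.get(profile)
    t0 = time.perf_counter()
    network = build_framework(framework, prof, seed)
    raster, decoded = _simulate_protocol(framework, network, prof, seed)
    rates = bin_spikes(raster, BIN_WIDTH)
    Z_pca = pca_modes(rates, 2)
    Z_fa = fa_modes(rates, 2)
    K = network.K.entries
    PhiT = network.decoders().T if hasattr(network, "decoders") \
        else network.Phi.T
    mats = {"K": K, "PhiT": PhiT, "Z_PCA": Z_pca.columns,
            "Z_FA": Z_fa.columns}
    names = list(mats)
    sim = pd.DataFrame(np.eye(4), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                c = subspace_cosine(mats[a], mats[b])
                sim.loc[a, b] = sim.loc[b, a] = c
    return {
        "framework": framework,
        "network": network,
        "raster": raster,
        "decoded": decoded,
        "binned": rates,
        "variance_explained": Z_pca.variance_explained,
        "modes_pca": Z_pca,
        "modes_fa": Z_fa,
        "similarity": sim,
        "wall_time_s": time.perf_counter() - t0,
        "seed": seed,
    }


SWEEP_KINDS = (
    PerturbationKind.identity,
    PerturbationKind.inside_permutation,
    PerturbationKind.inside_rot45,
    PerturbationKind.inside_gaussian,
    PerturbationKind.inside_same_element,
    PerturbationKind.outside_block_swap,
    PerturbationKind.redraw_K,
)


def _force_relearn(network: force_mod.ForceNetwork, K_new, profile: Profile,
                   schedule: force_mod.TrainingSchedule, relearn_seed: int):
    """Retrain Phi from scratch with new encoders, same reservoir/targets."""
    return force_mod.force_train(K_new, network.reservoir, schedule,
                                 dt=network.dt, seed=relearn_seed)


def run_perturbation_sweep(
    frameworks: Sequence[str] = FRAMEWORKS,
    n_instantiations: int = 5,
    profile: str = "desk",
    seed: int = 0,
    kinds: Sequence[PerturbationKind] = SWEEP_KINDS,
) -> pd.DataFrame:
    """Element-wise weight correlations W vs W-tilde per perturbation kind.

    For each instantiation a fresh network (fresh reservoir, encoders,
    tuning) is built and every perturbation kind applied and relearned
    with a fresh learning seed.  Rows: framework, kind, instantiation,
    correlation and Frobenius distance.
    """
    prof = Profile.get(profile)
    rows = []
    for fw in frameworks:
        for inst in range(n_instantiations):
            base_seed = _spawn(seed, _FW_ID[fw], inst)
            if fw == "force":
                target = make_step_targets(2, seed=_spawn(base_seed, 1),
                                           dt=prof.force_dt, **PROTOCOL)
                K = draw_encoders(EncoderScheme.uniform_box,
                                  prof.sweep_force_N, 2, 100.0,
                                  seed=_spawn(base_seed, 0))
                reservoir = force_mod.build_reservoir(
                    prof.sweep_force_N, seed=_spawn(base_seed, 2))
                schedule = force_mod.TrainingSchedule(
                    target, prof.sweep_force_total_s,
                    prof.sweep_force_learn_s)
                stride = max(1, round(5e-4 / prof.force_dt))
                network = force_mod.force_train(K, reservoir, schedule,
                                                dt=prof.force_dt,
                                                seed=_spawn(base_seed, 3),
                                                update_stride=stride)
            else:
                network = build_framework(fw, prof, base_seed)
            W_old = network.feedback_weights()
            for ci, kind in enumerate(kinds):
                pspec = make_perturbation(kind, network.K.N, network.K.D,
                                          seed=_spawn(base_seed, 20, ci))
                relearn_seed = _spawn(base_seed, 30, ci)
                if fw == "force":
                    K_new = perturb_encoders(network.K, pspec)
                    net_new = _force_relearn(network, K_new, prof, schedule,
                                             relearn_seed)
                    W_new = net_new.feedback_weights()
                else:
                    _, W_new, _ = perturb_and_relearn(network, pspec,
                                                      relearn_seed)
                rep = weight_similarity(W_old, W_new)
                rows.append(dict(framework=fw, kind=kind.value,
                                 instantiation=inst,
                                 correlation=rep.pearson_elementwise,
                                 frobenius=rep.frobenius_diff,
                                 frobenius_rel=rep.frobenius_diff
                                 / np.linalg.norm(W_old)))
    return pd.DataFrame(rows)


def run_oscillator_sweep(
    freqs_hz: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0),
    frameworks: Sequence[str] = ("nef", "ec"),
    profile: str = "desk",
    seed: int = 0,
    with_perturbations: bool = True,
) -> pd.DataFrame:
    """corr(K, Gamma^T) and perturbation weight correlations vs frequency.

    The same encoders and tuning are reused across the frequency grid
    so the curves vary only through the embedded dynamics
    Gamma = (tau_syn A + I) Phi.
    """
    prof = Profile.get(profile)
    rows = []
    for fw in frameworks:
        if fw not in ("nef", "ec"):
            raise ValueError(
                "the frequency sweep supports the batch frameworks only "
                "(the reservoir would need retraining per frequency)")
        base = build_framework(fw, prof, _spawn(seed, _FW_ID[fw]))
        for fi, f in enumerate(freqs_hz):
            A = oscillator_matrix(2.0 * np.pi * f)
            if fw == "nef":
                net = nef_mod.build_nef_network(
                    prof.nef_N, 2, seed=_spawn(seed, _FW_ID[fw]),
                    A_dyn=A, K=base.K, tuning=base.tuning,
                    eval_seed=base.eval_seed)
                Gamma = net.recurrent_decoders
            else:
                net = ec_mod.build_ec_network(base.K, base.tau_syn, base.mu,
                                              base.nu, A_dyn=A)
                Gamma = net.Gamma
            row = dict(framework=fw, f_hz=f,
                       corr_K_Gamma=columnwise_similarity(net.K.entries,
                                                          Gamma.T),
                       corr_K_Phi=columnwise_similarity(
                           net.K.entries,
                           (net.Phi if fw == "nef" else net.Phi).T))
            if with_perturbations:
                for kind in (PerturbationKind.inside_permutation,
                             PerturbationKind.outside_block_swap):
                    pspec = make_perturbation(kind, net.K.N, net.K.D,
                                              seed=_spawn(seed, 40, fi))
                    W_old, W_new, _ = perturb_and_relearn(
                        net, pspec, _spawn(seed, 50, fi))
                    rep = weight_similarity(W_old, W_new)
                    row[f"corr_W_{kind.value}"] = rep.pearson_elementwise
            rows.append(row)
    return pd.DataFrame(rows)


def run_daleian_network(profile: str = "desk", seed: int = 0,
                        n_perms: Optional[int] = None) -> dict:
    """Solve the sign-constrained network and compare all permutations.

    Builds the D=4 double-oscillator network under the shared sparsity
    and Dale mask, reports the weight statistics, then applies every
    non-identity latent permutation (inside), the matching 4-block row
    permutation (outside) and an independent encoder redraw, re-solving
    the weights each time and correlating with the original W.
    """
    prof = Profile.get(profile)
    t0 = time.perf_counter()
    network = dal.build_daleian_network(prof.daleian_N, 4,
                                        prof.daleian_n_eval, seed=seed)
    stats = dal.weight_statistics(network.weights)
    W_old = network.feedback_weights()
    from itertools import permutations as iter_perms

    perms = [p for p in iter_perms(range(4)) if p != (0, 1, 2, 3)]
    if n_perms is not None:
        perms = perms[:n_perms]
    rows = []
    for pi, perm in enumerate(perms):
        Q_in = permutation_matrix(np.array(perm))
        for cond in ("inside", "outside", "redraw"):
            rs = _spawn(seed, 60, pi, _COND_ID[cond])
            if cond == "inside":
                K_new = dal.EncoderMatrix(network.K.entries @ Q_in)
            elif cond == "outside":
                if network.N % 4:
                    raise ValueError("outside 4-block permutation needs N % 4 == 0")
                size = network.N // 4
                row_perm = np.concatenate(
                    [np.arange(size) + b * size for b in perm])
                K_new = dal.EncoderMatrix(network.K.entries[row_perm])
            else:
                K_new = draw_encoders(EncoderScheme.unit_sphere_rows,
                                      network.N, 4, seed=rs)
            net_new = dal.relearn_daleian(network, K_new, rs)
            rep = weight_similarity(W_old, net_new.feedback_weights())
            rows.append(dict(permutation="".join(str(p + 1) for p in perm),
                             condition=cond,
                             correlation=rep.pearson_elementwise,
                             frobenius=rep.frobenius_diff))
    table = pd.DataFrame(rows)
    from scipy.stats import ttest_rel

    inside = table.query("condition == 'inside'")["correlation"].to_numpy()
    outside = table.query("condition == 'outside'")["correlation"].to_numpy()
    redraw = table.query("condition == 'redraw'")["correlation"].to_numpy()
    t_in_out = ttest_rel(inside, outside, alternative="greater")
    t_out_redraw = ttest_rel(outside, redraw)
    return {
        "network": network,
        "stats": stats,
        "table": table,
        "inside_vs_outside_t": float(t_in_out.statistic),
        "inside_vs_outside_p": float(t_in_out.pvalue),
        "outside_vs_redraw_p": float(t_out_redraw.pvalue),
        "wall_time_s": time.perf_counter() - t0,
        "seed": seed,
    }


def run_latent_readout(profile: str = "desk", seed: int = 0,
                       perm: Sequence[int] = (2, 3, 0, 1),
                       network: Optional[dal.DaleianNetwork] = None,
                       duration: Optional[float] = None) -> dict:
    """Decode a permuted network with the unperturbed readout weights.

    Simulates the sign-constrained double-oscillator network and its
    inside-permuted relearned counterpart with no structured input,
    both primed on the attracting cycle (at this network scale the
    cycle is only transiently stable, so the frequency content is read
    from the first seconds while the oscillation persists), and
    estimates each latent pair's frequency from zero crossings.  For
    the permutation (3 4 1 2) the 2 Hz and 4 Hz pairs exchange
    positions in the old-decoder readout.
    """
    prof = Profile.get(profile)
    if network is None:
        network = dal.build_daleian_network(prof.daleian_N, 4,
                                            prof.daleian_n_eval, seed=seed)
    duration = prof.readout_duration_s if duration is None else duration
    Q = permutation_matrix(np.array(perm))
    K_new = dal.EncoderMatrix(network.K.entries @ Q)
    net_pert = dal.relearn_daleian(network, K_new, _spawn(seed, 70))
    x0 = np.array([1.0, 0.0, 1.0, 0.0])
    _, dec_base = dal.daleian_simulate(network, duration,
                                       seed=_spawn(seed, 71), x0=x0)
    _, dec_pert = dal.daleian_simulate(net_pert, duration,
                                       seed=_spawn(seed, 71), x0=x0,
                                       Phi_readout=network.Phi_readout)
    rec_dt = dec_base.dt
    window = slice(int(0.2 / rec_dt), None)
    freqs_base = np.array(
        [zero_crossing_frequency(dec_base.values[d, window], rec_dt,
                                 smooth_s=0.08) for d in range(4)])
    freqs_pert = np.array(
        [zero_crossing_frequency(dec_pert.values[d, window], rec_dt,
                                 smooth_s=0.08) for d in range(4)])
    return {
        "network": network,
        "perturbed": net_pert,
        "decoded_base": dec_base,
        "decoded_perturbed": dec_pert,
        "frequencies_base_hz": freqs_base,
        "frequencies_perturbed_hz": freqs_pert,
        "permutation": tuple(perm),
        "seed": seed,
    }


def run_dimension_scan(
    dims: Sequence[int] = (2, 4, 6, 8),
    profile: str = "desk",
    seed: int = 0,
    n_realizations: int = 3,
    subsample_fractions: Sequence[float] = (),
) -> pd.DataFrame:
    """Weight correlations vs latent dimensionality (batch framework).

    For each D, re-instantiation / inside permutation / outside
    permutation conditions are compared; the inside-vs-outside gap
    should persist as D grows.
    """
    prof = Profile.get(profile)
    rows = []
    for D in dims:
        for r in range(n_realizations):
            net = nef_mod.build_nef_network(prof.nef_N, D,
                                            seed=_spawn(seed, 80, D, r))
            W_old = net.feedback_weights()
            for kind in (PerturbationKind.identity,
                         PerturbationKind.inside_permutation,
                         PerturbationKind.outside_block_swap):
                pspec = make_perturbation(kind, net.K.N, D,
                                          seed=_spawn(seed, 81, D, r))
                _, W_new, _ = perturb_and_relearn(net, pspec,
                                                  _spawn(seed, 82, D, r))
                rows.append(dict(D=D, realization=r, kind=kind.value,
                                 correlation=weight_similarity(
                                     W_old, W_new).pearson_elementwise))
    return pd.DataFrame(rows)
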