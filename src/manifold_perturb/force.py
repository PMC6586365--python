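"""Echo-state spiking reservoir trained with FORCE / recursive least squares.

The network is a chaotic LIF reservoir (sparse random weights Omega,
loosely balanced so each neuron's mean input weight is zero) plus a
rank-D feedback loop W = K Phi.  The decoders Phi are adapted online
with the recursive-least-squares (RLS) rule while the network runs;
the helper matrix P tracks the inverse correlation of the filtered
spike trains u(t).

Units follow the normalized convention R_m = 1, V_th = 0,
V_reset = -1, V_leak = 0, which places the rheobase exactly at zero
current so the reservoir is tonically active without a drive current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from numba import njit

from .spiking import LIFParams, SpikeRaster
from .targets import EncoderMatrix, LatentTrajectory

#: Normalized LIF parameters of the reservoir neurons.
FORCE_LIF = LIFParams(
    tau_m=0.010, R_m=1.0, V_th=0.0, V_reset=-1.0, V_leak=0.0, t_ref=0.002
)

DEFAULT_TAU_SYN = 0.020
DEFAULT_DT = 5e-5
DEFAULT_P0 = 5e-6
DEFAULT_STRIDE = 10


@dataclass(frozen=True)
class ReservoirMatrix:
    """Sparse random reservoir weights Omega with gain G."""

    entries: np.ndarray
    sparsity_p: float
    G: float

    @property
    def N(self) -> int:
        return int(self.entries.shape[0])


@dataclass
class RLSState:
    """Recursive-least-squares state: P (inverse-correlation) and Phi."""

    P: np.ndarray
    Phi: np.ndarray
    update_stride: int = DEFAULT_STRIDE


@dataclass(frozen=True)
class TrainingSchedule:
    """FORCE training protocol.

    The target pattern is presented cyclically for ``total_s`` seconds;
    RLS updates run while t < ``learn_until_s``.  ``feedback_ramp``
    maps the fraction of elapsed learning time to [0, 1]: 0 means the
    target signal itself is fed into the network (open loop), 1 means
    the network's own decoded latents are fed back (closed loop).  The
    default ramps linearly to 1 over the first 40% of learning, leaving
    most of the learning phase fully closed-loop.
    """

    target: LatentTrajectory
    total_s: float
    learn_until_s: float
    feedback_ramp: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.learn_until_s > self.total_s:
            raise ValueError("learn_until_s must not exceed total_s")

    def ramp_values(self, n_steps: int, dt: float) -> np.ndarray:
        learn_steps = max(int(round(self.learn_until_s / dt)), 1)
        frac = np.minimum(np.arange(n_steps) / learn_steps, 1.0)
        if self.feedback_ramp is None:
            ramp = np.minimum(frac / 0.4, 1.0)
        else:
            ramp = np.array([self.feedback_ramp(f) for f in frac])
        ramp[np.arange(n_steps) * dt >= self.learn_until_s] = 1.0
        return np.clip(ramp, 0.0, 1.0)


def build_reservoir(N: int, p_nonzero: float = 0.1, G: float = 10.0,
                    seed: int = 0, balance: str = "nonzero") -> ReservoirMatrix:
    """Draw sparse random reservoir weights.

    Each entry is zero with probability 1 - p and otherwise normal with
    zero mean and standard deviation G / sqrt(p N).  Rows are then
    balanced so the mean input weight to each neuron is zero
    (``balance="nonzero"`` subtracts each row's mean from its nonzero
    entries; ``"all"`` subtracts the mean over all N entries instead).
    """
    if not 0 < p_nonzero <= 1:
        raise ValueError("p_nonzero must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sigma = G / math.sqrt(p_nonzero * N)
    mask = rng.random((N, N)) < p_nonzero
    entries = np.where(mask, rng.normal(0.0, sigma, (N, N)), 0.0)
    for j in range(N):
        nz = mask[j]
        if not nz.any():
            continue
        if balance == "nonzero":
            entries[j, nz] -= entries[j, nz].mean()
        elif balance == "all":
            entries[j, nz] -= entries[j].mean() * N / nz.sum()
        else:
            raise ValueError("balance must be 'nonzero' or 'all'")
    return ReservoirMatrix(entries, p_nonzero, G)


def rls_update(state: RLSState, u: np.ndarray, x: np.ndarray,
               x_target: np.ndarray) -> RLSState:
    """One recursive-least-squares step.

    P is updated first; Phi then uses the updated P, so that the gain
    vector P(t) u(t) equals the classical Kalman gain
    P(t-1) u / (1 + u' P(t-1) u).
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("non-finite filtered traces in RLS update")
    P = state.P
    Pu = P @ u
    denom = 1.0 + u @ Pu
    P_new = P - np.outer(Pu, Pu) / denom
    e = np.asarray(x, float) - np.asarray(x_target, float)
    Phi_new = state.Phi - np.outer(e, P_new @ u)
    return RLSState(P_new, Phi_new, state.update_stride)


@njit(cache=True)
def _force_loop(Omega, K, Phi, P, x_pattern, fix_mask, n_steps, dt, tau_m,
                tau_syn, ref_steps, v_th, v_reset, v_leak,
                learn_steps, stride, ramp, V0, record_stride,
                spike_cap):  # pragma: no cover - exercised via force_train
    N = Omega.shape[0]
    D = K.shape[1]
    Tp = x_pattern.shape[1]
    u = np.zeros(N)
    V = V0.copy()
    ref = np.zeros(N, np.int64)
    decay_m = math.exp(-dt / tau_m)
    decay_s = math.exp(-dt / tau_syn)
    n_rec = n_steps // record_stride
    dec_hist = np.zeros((D, n_rec))
    spike_ids = np.empty(spike_cap, np.int64)
    spike_ts = np.empty(spike_cap, np.float64)
    n_sp = 0
    last_spike_step = 0
    longest_gap = 0
    for t in range(n_steps):
        tp = t % Tp
        x_dec = Phi @ u
        if fix_mask[tp]:
            x_fb = x_pattern[:, tp]
        else:
            r = ramp[t]
            x_fb = r * x_dec + (1.0 - r) * x_pattern[:, tp]
        I = Omega @ u + K @ x_fb
        spiked = False
        for j in range(N):
            V_inf = v_leak + I[j]
            V[j] = V_inf + (V[j] - V_inf) * decay_m
            u[j] *= decay_s
            if ref[j] > 0:
                V[j] = v_reset
                ref[j] -= 1
            elif V[j] >= v_th:
                V[j] = v_reset
                ref[j] = ref_steps
                u[j] += 1.0
                spiked = True
                if n_sp < spike_cap:
                    spike_ids[n_sp] = j
                    spike_ts[n_sp] = t * dt
                    n_sp += 1
        if spiked:
            if t - last_spike_step > longest_gap:
                longest_gap = t - last_spike_step
            last_spike_step = t
        if t < learn_steps and t % stride == 0:
            Pu = P @ u
            denom = 1.0 + u @ Pu
            for a in range(N):
                for b in range(N):
                    P[a, b] -= Pu[a] * Pu[b] / denom
            Pu2 = P @ u
            x_now = Phi @ u
            for d in range(D):
                e_d = x_now[d] - x_pattern[d, tp]
                for b in range(N):
                    Phi[d, b] -= e_d * Pu2[b]
        if t % record_stride == 0:
            dec_hist[:, t // record_stride] = x_dec
    if n_steps - last_spike_step > longest_gap:
        longest_gap = n_steps - last_spike_step
    return Phi, P, dec_hist, spike_ids[:n_sp], spike_ts[:n_sp], longest_gap


@dataclass
class ForceNetwork:
    """A trained (or untrained) FORCE network."""

    K: EncoderMatrix
    reservoir: ReservoirMatrix
    Phi: np.ndarray
    params: LIFParams = FORCE_LIF
    tau_syn: float = DEFAULT_TAU_SYN
    dt: float = DEFAULT_DT
    diagnostics: dict = field(default_factory=dict)

    def feedback_weights(self) -> np.ndarray:
        """The learnable feedback component W = K Phi (reservoir excluded)."""
        return self.K.entries @ self.Phi

    def decoders(self) -> np.ndarray:
        return self.Phi

    def to_npz(self, path, **provenance) -> None:
        """Persist (K, Phi, Omega) plus parameters and provenance keys."""
        np.savez(path, K=self.K.entries, Phi=self.Phi,
                 Omega=self.reservoir.entries,
                 sparsity_p=self.reservoir.sparsity_p, G=self.reservoir.G,
                 tau_syn=self.tau_syn, dt=self.dt,
                 **{f"meta_{k}": v for k, v in provenance.items()})

    @classmethod
    def from_npz(cls, path) -> "ForceNetwork":
        with np.load(path) as d:
            K = EncoderMatrix(d["K"])
            res = ReservoirMatrix(d["Omega"], float(d["sparsity_p"]),
                                  float(d["G"]))
            return cls(K, res, d["Phi"], FORCE_LIF, float(d["tau_syn"]),
                       float(d["dt"]))


def _run(network: ForceNetwork, schedule: TrainingSchedule, seed: int,
         learn: bool, P0_scale: float, stride: int, record_stride: int,
         Phi0: Optional[np.ndarray] = None):
    dt = network.dt
    target = schedule.target
    if abs(target.dt / dt - round(target.dt / dt)) > 1e-9:
        raise ValueError("target grid must be an integer multiple of dt")
    rep = int(round(target.dt / dt))
    x_pattern = np.repeat(target.values, rep, axis=1)
    fix_mask = np.repeat(target.fixation_mask, rep)
    n_steps = int(round(schedule.total_s / dt))
    learn_steps = int(round(schedule.learn_until_s / dt)) if learn else 0
    ramp = schedule.ramp_values(n_steps, dt)
    rng = np.random.default_rng(seed)
    V0 = rng.uniform(network.params.V_reset, network.params.V_th,
                     network.reservoir.N)
    D = target.D
    Phi = np.zeros((D, network.reservoir.N)) if Phi0 is None else Phi0.copy()
    P = P0_scale * np.eye(network.reservoir.N)
    spike_cap = int(network.reservoir.N * schedule.total_s * 520) + 1000
    p = network.params
    Phi, P, dec, sp_ids, sp_ts, gap = _force_loop(
        network.reservoir.entries, network.K.entries, Phi, P,
        np.ascontiguousarray(x_pattern), fix_mask, n_steps, dt, p.tau_m,
        network.tau_syn, int(round(p.t_ref / dt)), p.V_th, p.V_reset,
        p.V_leak, learn_steps, stride, ramp, V0, record_stride, spike_cap)
    raster = SpikeRaster(sp_ids, sp_ts, network.reservoir.N, schedule.total_s)
    diagnostics = {
        "longest_silent_gap_s": gap * dt,
        "silent_warning": gap * dt > 0.1,
        "n_spikes": raster.n_spikes,
        "mean_rate_hz": raster.n_spikes / (network.reservoir.N * schedule.total_s),
    }
    times = np.arange(dec.shape[1]) * dt * record_stride
    decoded = LatentTrajectory(times, dec, np.zeros(times.size, bool)) \
        if times.size > 1 else None
    return Phi, P, decoded, raster, diagnostics


def force_train(
    K: EncoderMatrix,
    reservoir: ReservoirMatrix,
    schedule: TrainingSchedule,
    params: LIFParams = FORCE_LIF,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    tau_syn: float = DEFAULT_TAU_SYN,
    P0_scale: float = DEFAULT_P0,
    update_stride: int = DEFAULT_STRIDE,
    record_stride: int = 20,
) -> ForceNetwork:
    """Train the decoders Phi with FORCE and return the trained network.

    The network is exposed cyclically to the target pattern; while
    learning is active the RLS rule updates Phi every
    ``update_stride``-th step with P(0) = ``P0_scale`` * I and
    Phi(0) = 0.  The feedback current ramps from the target signal
    (open loop) to the decoded latents (closed loop) according to the
    schedule.
    """
    net = ForceNetwork(K, reservoir, np.zeros((schedule.target.D, reservoir.N)),
                       params, tau_syn, dt)
    Phi, P, decoded, raster, diag = _run(
        net, schedule, seed, learn=True, P0_scale=P0_scale,
        stride=update_stride, record_stride=record_stride)
    if diag["silent_warning"]:
        import warnings

        warnings.warn(
            f"reservoir silent for {diag['longest_silent_gap_s']:.3f}s during training",
            RuntimeWarning,
        )
    diag["decoded"] = decoded
    diag["raster"] = raster
    return replace(net, Phi=Phi, diagnostics=diag)


def force_simulate(
    network: ForceNetwork,
    targets: LatentTrajectory,
    seed: int = 0,
    record_stride: int = 20,
) -> tuple[SpikeRaster, LatentTrajectory]:
    """Run the trained network closed-loop (no learning).

    The latents are clamped to the target values wherever the target's
    fixation mask is set and evolve freely in between.
    """
    schedule = TrainingSchedule(targets, targets.duration, 0.0)
    _, _, decoded, raster, diag = _run(
        network, schedule, seed, learn=False, P0_scale=1.0,
        stride=DEFAULT_STRIDE, record_stride=record_stride,
        Phi0=network.Phi)
    return raster, decoded
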