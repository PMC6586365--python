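"""Efficient-coding spiking network with analytically fixed weights.

No learning: the decoders are Phi = lambda_syn K^T, the slow recurrent
weights W = lambda_syn K K^T, and the fast (instantaneous) weights
Omega = -K K^T - mu lambda^2 I, with per-neuron thresholds
V_th,j = (nu lambda + mu lambda^2 + ||k_j||^2) / 2.  Each spike of
neuron i instantaneously decrements the voltages by column i of the
fast matrix; the inhibitory autapse (diagonal) replaces an explicit
reset.  Spikes greedily keep the decoded latents x = Phi u close to
the signal the network is driven with.

In the exact derivation of this network class the voltage of neuron j
equals the projection k_j . (x - x_hat) of the coding error, whose
dynamics already contain the decay that the membrane leak would
provide; the leak is canceled by a matching V-proportional component
of the derived recurrent current.  The simulation therefore integrates
the slow and external currents without an additional leak (with the
leak left uncompensated the decoded variables decay toward zero within
about a second instead of being retained).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit

from .spiking import LIFParams, SpikeRaster
from .targets import EncoderMatrix, LatentTrajectory

EC_LIF = LIFParams(tau_m=0.050, R_m=1.0, V_th=1.0, V_reset=0.0,
                   V_leak=0.0, t_ref=0.0)

DEFAULT_TAU_SYN = 0.020
DEFAULT_MU = 1e-6
DEFAULT_NU = 1e-3
DEFAULT_DT = 1e-4
#: The latent values used in simulation are this factor larger than the
#: nominal task values; decoded traces are scaled back for comparison.
LATENT_SCALE = 100.0


#: Standard deviation of the i.i.d. normal encoder entries.  With the
#: x100 latent scale this puts the per-spike decode step
#: lambda * ||k_j|| at roughly 2% of the signal scale, giving sparse
#: (~1.5 Hz) asynchronous firing that still identifies the modes
#: within a 2.5 s protocol while retaining clamped values to a few
#: percent.
EC_ENCODER_SIGMA = 0.025


def draw_ec_encoders(N: int, D: int, seed: int = 0,
                     sigma: float = EC_ENCODER_SIGMA) -> EncoderMatrix:
    """Random encoders for the efficient-coding network.

    Entries are i.i.d. normal with standard deviation ``sigma``; the
    heterogeneous row norms spread the per-neuron thresholds, which
    desynchronizes the population.
    """
    rng = np.random.default_rng(seed)
    return EncoderMatrix(sigma * rng.standard_normal((N, D)))


def default_ec_encoder_scale(tau_syn: float = DEFAULT_TAU_SYN,
                             mu: float = DEFAULT_MU,
                             nu: float = DEFAULT_NU) -> float:
    """Row norm minimizing the single-neuron error dead-zone.

    The per-spike decode step grows with ||k|| while the spike
    threshold carries the fixed costs nu*lambda + mu*lambda^2; the
    dead-zone (nu lambda + mu lambda^2 + ||k||^2) / (2 ||k||) is
    minimized at ||k|| = sqrt(nu lambda + mu lambda^2).  Retention is
    best near this norm, but firing is then so sparse that mode
    identification from 2.5 s of binned counts is shot-noise limited;
    the package default therefore uses :func:`draw_ec_encoders`.
    """
    lam = 1.0 / tau_syn
    return float(np.sqrt(nu * lam + mu * lam**2))


@dataclass(frozen=True)
class ECNetwork:
    """An efficient-coding network; every weight follows from K."""

    K: EncoderMatrix
    lambda_syn: float
    mu: float = DEFAULT_MU
    nu: float = DEFAULT_NU
    threshold_convention: str = "halved"
    #: recurrent decoders (Gamma) if latent dynamics are embedded, else None
    A_dyn: Optional[np.ndarray] = None

    @property
    def N(self) -> int:
        return self.K.N

    @property
    def D(self) -> int:
        return self.K.D

    @property
    def tau_syn(self) -> float:
        return 1.0 / self.lambda_syn

    @property
    def Phi(self) -> np.ndarray:
        """Readout decoders Phi = lambda K^T (D x N)."""
        return self.lambda_syn * self.K.entries.T

    @property
    def Gamma(self) -> np.ndarray:
        """Recurrent decoders (tau A + I) lambda K^T; Phi when A is None."""
        if self.A_dyn is None:
            return self.Phi
        D = self.K.D
        return (self.tau_syn * self.A_dyn + np.eye(D)) @ self.Phi

    @property
    def W_slow(self) -> np.ndarray:
        """Slow feedback weights K Gamma (= lambda K K^T for the integrator)."""
        return self.K.entries @ self.Gamma

    @property
    def Omega_fast(self) -> np.ndarray:
        """Instantaneous weights -K K^T - mu lambda^2 I (incl. autapses)."""
        KKt = self.K.entries @ self.K.entries.T
        return -KKt - self.mu * self.lambda_syn**2 * np.eye(self.N)

    @property
    def thresholds(self) -> np.ndarray:
        """Per-neuron spiking thresholds from nu, mu, lambda and ||k_j||."""
        k2 = np.sum(self.K.entries**2, axis=1)
        raw = self.nu * self.lambda_syn + self.mu * self.lambda_syn**2 + k2
        if self.threshold_convention == "halved":
            return raw / 2.0
        elif self.threshold_convention == "unhalved":
            return raw
        raise ValueError("threshold_convention must be 'halved' or 'unhalved'")

    def feedback_weights(self) -> np.ndarray:
        """The learnable component W = K Gamma (fast weights excluded)."""
        return self.W_slow

    def decoders(self) -> np.ndarray:
        return self.Phi


def build_ec_network(
    K: EncoderMatrix,
    tau_syn: float = DEFAULT_TAU_SYN,
    mu: float = DEFAULT_MU,
    nu: float = DEFAULT_NU,
    A_dyn: Optional[np.ndarray] = None,
    threshold_convention: str = "halved",
) -> ECNetwork:
    """Assemble the network; all weights are deterministic functions of K."""
    if not np.all(np.isfinite(K.entries)):
        raise ValueError("encoders must be finite")
    return ECNetwork(K, 1.0 / tau_syn, mu, nu, threshold_convention, A_dyn)


def ec_dynamics_weights(net: ECNetwork, A: np.ndarray) -> np.ndarray:
    """Slow weights K Gamma with Gamma = (tau A + I) lambda K^T."""
    return replace(net, A_dyn=np.asarray(A, float)).W_slow


@njit(cache=True)
def _ec_loop(K, W_slow, Omega_fast, thresholds, x_cmd_T, fix_mask, dt, tau_m,
             tau_syn, Phi, V0, max_spikes_per_step,
             spike_cap):  # pragma: no cover - exercised via ec_simulate
    N, D = K.shape
    T = x_cmd_T.shape[0]
    lam = 1.0 / tau_syn
    decay_m = math.exp(-dt / tau_m)
    decay_s = math.exp(-dt / tau_syn)
    V = V0.copy()
    u = np.zeros(N)
    decoded = np.empty((D, T))
    spike_ids = np.empty(spike_cap, np.int64)
    spike_ts = np.empty(spike_cap, np.float64)
    n_sp = 0
    for t in range(T):
        if fix_mask[t]:
            # clamp drive: slow feedback replaced by the target values;
            # the decoded latents then relax to the target with rate lambda
            I = K @ x_cmd_T[t]
        else:
            I = W_slow @ u
        # leak-compensated integration: V_j equals the projected coding
        # error, whose own decay already absorbs the membrane leak term
        for j in range(N):
            V[j] += dt * I[j]
        u *= decay_s
        # one spike at a time: largest suprathreshold overshoot first,
        # fast synapses applied before re-testing
        for _ in range(max_spikes_per_step):
            best = -1
            best_over = 0.0
            for j in range(N):
                over = V[j] - thresholds[j]
                if over > best_over:
                    best_over = over
                    best = j
            if best < 0:
                break
            V += Omega_fast[:, best]
            u[best] += 1.0
            if n_sp < spike_cap:
                spike_ids[n_sp] = best
                spike_ts[n_sp] = t * dt
                n_sp += 1
        for d in range(D):
            acc = 0.0
            for j in range(N):
                acc += Phi[d, j] * u[j]
            decoded[d, t] = acc
    return decoded, spike_ids[:n_sp], spike_ts[:n_sp]


def ec_simulate(
    net: ECNetwork,
    targets: LatentTrajectory,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    max_rate_hz: float = 1000.0,
    max_spikes_per_step: int = 100,
) -> tuple[SpikeRaster, LatentTrajectory]:
    """Simulate the network and decode x = Phi u.

    ``targets`` supplies the clamp schedule: wherever its fixation mask
    is set, the slow feedback is replaced by a drive current
    tau_m * lambda * K x_target, which relaxes the decoded latents to
    the target with time constant tau_syn; elsewhere the network runs
    autonomously on its slow recurrence.  Targets are expected on the
    simulation scale (use ``LatentTrajectory.scaled`` for the x100
    convention).
    """
    if abs(targets.dt - dt) > 1e-12:
        raise ValueError("target grid must match the simulation dt")
    N = net.N
    rng = np.random.default_rng(seed)
    th = net.thresholds
    # V_j = k_j . (x - x_hat) = 0 at t = 0; a tiny seeded jitter breaks
    # exact ties between identical neurons
    V0 = rng.uniform(-1e-6, 1e-6, N) * th
    cap = int(N * targets.duration * max_rate_hz * 2) + 1000
    decoded, ids, ts = _ec_loop(
        np.ascontiguousarray(net.K.entries), net.W_slow, net.Omega_fast, th,
        np.ascontiguousarray(targets.values.T), targets.fixation_mask, dt,
        EC_LIF.tau_m, net.tau_syn, np.ascontiguousarray(net.Phi), V0,
        max_spikes_per_step, cap)
    mean_rate = ids.size / (N * targets.duration)
    if mean_rate > max_rate_hz:
        raise RuntimeError(
            f"runaway firing ({mean_rate:.0f} Hz mean): increase mu or reduce dt")
    raster = SpikeRaster(ids, ts, N, targets.duration)
    return raster, LatentTrajectory(targets.times, decoded, targets.fixation_mask)
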