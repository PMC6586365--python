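"""Neural Engineering Framework: tuning curves, batch decoders, dynamics.

Each neuron j receives the current gain_j * (k_j . x) + bias_j, where
k_j (a row of the encoder matrix K, unit norm) is the neuron's
preferred direction in latent space.  Gains and biases are calibrated
from a drawn maximal rate and an intercept, using the closed-form LIF
rate curve.  The decoders Phi are found in batch: least squares from
the expected activities at a cloud of evaluation points onto the
target latent values.  Latent dynamics dx/dt = A x are embedded by
replacing Phi with Gamma = (tau_syn A + I) Phi on the recurrent loop.

Convention: activities are expressed in Hz and the decoders returned
by :func:`solve_decoders` act on rates in Hz.  The spiking readout
x = Phi u uses the rate estimate u(t) / tau_syn, where u is the
unit-increment exponentially filtered spike train (its mean is
rate * tau_syn).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .spiking import LIFParams, SpikeRaster, lif_rate
from .targets import EncoderMatrix, EncoderScheme, LatentTrajectory, draw_encoders

#: Default LIF parameters (membrane 20 ms, refractory 2 ms, unit threshold).
NEF_LIF = LIFParams(tau_m=0.020, R_m=1.0, V_th=1.0, V_reset=0.0,
                    V_leak=0.0, t_ref=0.002)

DEFAULT_TAU_SYN = 0.010
DEFAULT_DT = 1e-3
DEFAULT_MAX_RATES = (80.0, 120.0)
DEFAULT_N_EVAL = 2000
DEFAULT_RIDGE = 0.01


@dataclass(frozen=True)
class NeuronTuning:
    """Per-neuron gains and biases plus the draws that produced them."""

    gains: np.ndarray
    biases: np.ndarray
    max_rates: np.ndarray
    intercepts: np.ndarray


@dataclass(frozen=True)
class EvaluationSet:
    """Sample points of x_target used for the batch decoder solve."""

    points: np.ndarray  # (M, D)
    domain: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, float))
        lo, hi = self.domain
        if pts.min() < lo - 1e-12 or pts.max() > hi + 1e-12:
            raise ValueError("evaluation points must lie inside the domain")
        object.__setattr__(self, "points", pts)

    @property
    def M(self) -> int:
        return int(self.points.shape[0])


def _rate_to_current(rate: float, params: LIFParams) -> float:
    """Invert the LIF f-I curve (normalized V_th=1, V_reset=0)."""
    if rate <= 0 or rate >= 1.0 / max(params.t_ref, 1e-12):
        raise ValueError("rate must be positive and below the refractory ceiling")
    q = (1.0 / rate - params.t_ref) / params.tau_m
    return 1.0 / (1.0 - np.exp(-q))


def calibrate_gain_bias(
    N: int,
    max_rates: tuple[float, float] = DEFAULT_MAX_RATES,
    params: LIFParams = NEF_LIF,
    seed: int = 0,
) -> NeuronTuning:
    """Draw max rates and intercepts; solve gains and biases per neuron.

    For each neuron, the maximal rate is uniform in ``max_rates`` and
    the intercept uniform in [-1, 1).  The two defining conditions are
    rate = 0 at x = intercept (along the preferred direction) and
    rate = max_rate at x = 1, giving a 2x2 linear system for
    (gain, bias) through the rheobase current J = 1:
    gain * intercept + bias = 1 and gain + bias = J_max.
    """
    rng = np.random.default_rng(seed)
    rates = rng.uniform(max_rates[0], max_rates[1], N)
    intercepts = rng.uniform(-1.0, 1.0, N)
    ceiling = 1.0 / max(params.t_ref, 1e-12)
    if max_rates[1] >= ceiling:
        raise ValueError("max rates exceed the refractory ceiling 1/t_ref")
    J_max = np.array([_rate_to_current(r, params) for r in rates])
    gains = (J_max - 1.0) / (1.0 - intercepts)
    biases = 1.0 - gains * intercepts
    return NeuronTuning(gains, biases, rates, intercepts)


def sample_evaluation_points(
    D: int,
    M: int = DEFAULT_N_EVAL,
    domain: tuple[float, float] = (-1.0, 1.0),
    seed: int = 0,
) -> EvaluationSet:
    """Uniform samples from the box ``domain``^D."""
    if M < D:
        raise ValueError("need at least D evaluation points")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(domain[0], domain[1], size=(M, D))
    return EvaluationSet(pts, domain)


def estimate_activities(
    tuning: NeuronTuning,
    K: EncoderMatrix,
    eval_set: EvaluationSet,
    params: LIFParams = NEF_LIF,
) -> np.ndarray:
    """Expected firing rates (M x N, Hz) at each evaluation point."""
    drive = eval_set.points @ K.entries.T * tuning.gains + tuning.biases
    return lif_rate(drive, params)


def solve_decoders(
    activities: np.ndarray,
    targets: np.ndarray,
    ridge: float = DEFAULT_RIDGE,
) -> np.ndarray:
    """Regularized least squares for the decoders (D x N, Hz convention).

    Minimizes <|| x_target - Phi' a ||^2> over the evaluation set with
    ridge regularization sigma = ridge * max|activities| (so that
    Phi^T = (A^T A + M sigma^2 I)^{-1} A^T X).
    """
    A = np.atleast_2d(np.asarray(activities, float))
    X = np.atleast_2d(np.asarray(targets, float))
    if X.shape[0] != A.shape[0]:
        X = X.T
    M, N = A.shape
    if M < X.shape[1]:
        raise ValueError("need at least D evaluation points")
    sigma = ridge * np.abs(A).max()
    G = A.T @ A + M * sigma**2 * np.eye(N)
    if sigma == 0 and np.linalg.matrix_rank(A) < N:
        raise np.linalg.LinAlgError(
            "rank-deficient activities require ridge > 0")
    PhiT = np.linalg.solve(G, A.T @ X)
    return PhiT.T


def dynamics_transform(A: np.ndarray, Phi: np.ndarray, tau_syn: float) -> np.ndarray:
    """Embed dx/dt = A x into the recurrent decoders: Gamma = (tau A + I) Phi."""
    A = np.asarray(A, float)
    return (tau_syn * A + np.eye(A.shape[0])) @ Phi


def assemble_weights(K: EncoderMatrix, decoders: np.ndarray,
                     gains: Optional[np.ndarray] = None) -> np.ndarray:
    """Fold the factored loop into one synaptic matrix W = diag(g) K Phi."""
    W = K.entries @ decoders
    if gains is not None:
        W = W * np.asarray(gains, float)[:, None]
    return W


@dataclass
class NEFNetwork:
    """A built NEF network: encoders, tuning, and batch-solved decoders.

    ``Phi`` is the plain latent decoder; ``recurrent_decoders`` is what
    the feedback loop actually decodes (equal to Phi for the
    integrator, Gamma for latent dynamics).  Both are in Hz units.
    """

    K: EncoderMatrix
    tuning: NeuronTuning
    Phi: np.ndarray
    recurrent_decoders: np.ndarray
    eval_seed: int
    params: LIFParams = NEF_LIF
    tau_syn: float = DEFAULT_TAU_SYN
    dt: float = DEFAULT_DT
    ridge: float = DEFAULT_RIDGE
    n_eval: int = DEFAULT_N_EVAL
    A_dyn: Optional[np.ndarray] = None

    @property
    def N(self) -> int:
        return self.K.N

    @property
    def D(self) -> int:
        return self.K.D

    def feedback_weights(self) -> np.ndarray:
        """The synaptic feedback component, current per unit rate (Hz)."""
        return assemble_weights(self.K, self.recurrent_decoders, self.tuning.gains)


def build_nef_network(
    N: int = 1000,
    D: int = 2,
    seed: int = 0,
    A_dyn: Optional[np.ndarray] = None,
    K: Optional[EncoderMatrix] = None,
    tuning: Optional[NeuronTuning] = None,
    eval_seed: Optional[int] = None,
    n_eval: int = DEFAULT_N_EVAL,
    ridge: float = DEFAULT_RIDGE,
    tau_syn: float = DEFAULT_TAU_SYN,
    max_rates: tuple[float, float] = DEFAULT_MAX_RATES,
    params: LIFParams = NEF_LIF,
) -> NEFNetwork:
    """Build (and batch-'learn') an NEF network.

    The base seed fixes the encoder and tuning draws; ``eval_seed``
    (defaulting to a fixed offset of ``seed``) fixes the
    learning-phase randomness, i.e. the evaluation-point sample, so
    relearning with fresh evaluation points models restarting the
    learning algorithm.
    """
    rng = np.random.default_rng(seed)
    if K is None:
        K = draw_encoders(EncoderScheme.unit_sphere_rows, N, D,
                          seed=rng.integers(2**31))
    tuning_seed = int(rng.integers(2**31))
    if tuning is None:
        tuning = calibrate_gain_bias(K.N, max_rates, params, seed=tuning_seed)
    if eval_seed is None:
        eval_seed = int(rng.integers(2**31))
    eval_set = sample_evaluation_points(K.D, n_eval, seed=eval_seed)
    activities = estimate_activities(tuning, K, eval_set, params)
    Phi = solve_decoders(activities, eval_set.points, ridge)
    if A_dyn is not None:
        recurrent = dynamics_transform(A_dyn, Phi, tau_syn)
    else:
        recurrent = Phi
    return NEFNetwork(K, tuning, Phi, recurrent, eval_seed, params,
                      tau_syn, DEFAULT_DT, ridge, n_eval,
                      None if A_dyn is None else np.asarray(A_dyn, float))


def relearn_nef(network: NEFNetwork, K_new: EncoderMatrix,
                relearn_seed: int) -> NEFNetwork:
    """Re-run the batch decoder solve with new encoders.

    Neuron identities (gains, biases) and all hyperparameters are kept;
    only the encoders and the learning-phase randomness (the
    evaluation-point draw) change.
    """
    eval_set = sample_evaluation_points(K_new.D, network.n_eval,
                                        seed=relearn_seed)
    activities = estimate_activities(network.tuning, K_new, eval_set,
                                     network.params)
    Phi = solve_decoders(activities, eval_set.points, network.ridge)
    if network.A_dyn is not None:
        recurrent = dynamics_transform(network.A_dyn, Phi, network.tau_syn)
    else:
        recurrent = Phi
    return replace(network, K=K_new, Phi=Phi, recurrent_decoders=recurrent,
                   eval_seed=relearn_seed)


def nef_simulate(
    network: NEFNetwork,
    targets: LatentTrajectory,
    seed: int = 0,
    Phi_readout: Optional[np.ndarray] = None,
) -> tuple[SpikeRaster, LatentTrajectory]:
    """Closed-loop spiking simulation with optional latent clamping.

    During fixation steps the feedback current is computed from the
    target latents instead of the decoded ones (the relay-node
    protocol); elsewhere the loop is closed through the recurrent
    decoders.  Returns the spike raster and decoded latents.
    """
    p = network.params
    dt = network.dt
    if abs(targets.dt - dt) > 1e-12:
        raise ValueError("target grid must match the simulation dt")
    T = targets.times.size
    N, D = network.N, network.D
    rng = np.random.default_rng(seed)
    V = rng.uniform(p.V_reset, p.V_th, N)
    u = np.zeros(N)
    decay_m = np.exp(-dt / p.tau_m)
    decay_s = np.exp(-dt / network.tau_syn)
    ref_steps = int(round(p.t_ref / dt))
    ref = np.zeros(N, dtype=int)
    Kg = network.K.entries * network.tuning.gains[:, None]
    Phi_rec = network.recurrent_decoders / network.tau_syn
    Phi_out = (network.Phi if Phi_readout is None else Phi_readout) / network.tau_syn
    decoded = np.empty((D, T))
    spike_ids, spike_steps = [], []
    for t in range(T):
        x_dec = Phi_out @ u
        x_rec = Phi_rec @ u
        if targets.fixation_mask[t]:
            x_fb = targets.values[:, t]
        else:
            x_fb = x_rec
        I = Kg @ x_fb + network.tuning.biases
        V_inf = p.V_leak + p.R_m * I
        V = V_inf + (V - V_inf) * decay_m
        refractory = ref > 0
        V[refractory] = p.V_reset
        ref[refractory] -= 1
        fired = (V >= p.V_th) & ~refractory
        u *= decay_s
        if fired.any():
            idx = np.flatnonzero(fired)
            V[idx] = p.V_reset
            ref[idx] = ref_steps
            u[idx] += 1.0
            spike_ids.append(idx)
            spike_steps.append(np.full(idx.size, t))
        decoded[:, t] = x_dec
    if spike_ids:
        ids = np.concatenate(spike_ids)
        ts = np.concatenate(spike_steps) * dt
    else:
        ids, ts = np.empty(0, np.int64), np.empty(0)
    raster = SpikeRaster(ids, ts, N, targets.duration)
    return raster, LatentTrajectory(targets.times, decoded, targets.fixation_mask)
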