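"""Leaky integrate-and-fire substrate shared by all network frameworks.

Provides the membrane integration (exponential-Euler, exact for the
linear part of the LIF equation), exponential synaptic filtering of
spike trains, spike binning into the count matrix used for PCA /
factor analysis, and the closed-form stationary LIF rate used to
calibrate tuning curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np
from scipy.signal import lfilter


@dataclass(frozen=True)
class LIFParams:
    """Parameters of a population of LIF neurons (normalized units).

    ``tau_m`` is the membrane time constant (s), ``R_m`` the input
    resistance, ``V_th``/``V_reset``/``V_leak`` the threshold, reset
    and resting voltages, ``t_ref`` the absolute refractory period (s).
    ``per_neuron_thresholds`` optionally overrides ``V_th`` with an
    N-vector (used by the efficient-coding network, where thresholds
    depend on each neuron's encoder row).
    """

    tau_m: float = 0.02
    R_m: float = 1.0
    V_th: float = 1.0
    V_reset: float = 0.0
    V_leak: float = 0.0
    t_ref: float = 0.002
    per_neuron_thresholds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")
        if self.per_neuron_thresholds is not None:
            th = np.asarray(self.per_neuron_thresholds, dtype=float)
            if np.any(th < self.V_reset):
                raise ValueError("V_reset must not exceed any threshold")
            object.__setattr__(self, "per_neuron_thresholds", th)
        elif self.V_reset > self.V_th:
            raise ValueError("V_reset must not exceed V_th")

    def thresholds(self, N: int) -> np.ndarray:
        if self.per_neuron_thresholds is not None:
            if self.per_neuron_thresholds.size != N:
                raise ValueError("per_neuron_thresholds length mismatch")
            return self.per_neuron_thresholds
        return np.full(N, self.V_th)


@dataclass(frozen=True)
class SpikeRaster:
    """Event-level spikes: parallel arrays of neuron ids and times."""

    neuron_ids: np.ndarray
    times: np.ndarray
    N: int
    duration: float

    def __post_init__(self) -> None:
        ids = np.asarray(self.neuron_ids, dtype=np.int64)
        times = np.asarray(self.times, dtype=float)
        if ids.shape != times.shape:
            raise ValueError("neuron_ids and times must have equal length")
        if times.size and (times.min() < 0 or times.max() > self.duration):
            raise ValueError("spike times must lie within [0, duration]")
        if ids.size and (ids.min() < 0 or ids.max() >= self.N):
            raise ValueError("neuron ids out of range")
        object.__setattr__(self, "neuron_ids", ids)
        object.__setattr__(self, "times", times)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def spikes_of(self, j: int) -> np.ndarray:
        return np.sort(self.times[self.neuron_ids == j])

    def to_txt(self, path: Union[str, Path]) -> None:
        """Two-column delimited event table (neuron_id, time_s)."""
        np.savetxt(
            path,
            np.column_stack([self.neuron_ids, self.times]),
            fmt=["%d", "%.9f"],
            delimiter="\t",
            header=f"neuron_id\ttime_s\t# N={self.N} duration={self.duration}",
            comments="",
        )


@dataclass(frozen=True)
class BinnedRates:
    """Spike counts per neuron per consecutive bin (N x B integers)."""

    counts: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def N(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.counts.shape[1])

    def to_txt(self, path: Union[str, Path]) -> None:
        """Delimited count matrix (neurons x bins) with bin metadata."""
        np.savetxt(path, self.counts, fmt="%d", delimiter="\t",
                   header=f"bin_width_s={self.bin_width}")

    @classmethod
    def from_txt(cls, path: Union[str, Path]) -> "BinnedRates":
        with open(path) as fh:
            header = fh.readline()
        bin_width = float(header.strip().lstrip("# ").split("=")[1])
        counts = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        return cls(counts.astype(np.int64), bin_width)


@dataclass(frozen=True)
class FilteredTraces:
    """Synaptically filtered spike trains u(t) on the simulation grid."""

    u: np.ndarray
    tau_syn: float
    dt: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.u.shape[1]) * self.dt


def exp_kernel(t: Union[float, np.ndarray], tau_syn: float) -> np.ndarray:
    """Causal exponential synaptic kernel: 0 for t<0, e^(-t/tau) for t>=0."""
    if tau_syn <= 0:
        raise ValueError("tau_syn must be positive")
    t = np.asarray(t, dtype=float)
    return np.where(t < 0, 0.0, np.exp(-np.clip(t, 0.0, None) / tau_syn))


def filter_spikes(raster: SpikeRaster, tau_syn: float, dt: float) -> FilteredTraces:
    """Convolve each neuron's spike train with the exponential kernel.

    Implemented as the discrete leaky trace u <- u * exp(-dt/tau) with a
    unit increment at each spike, evaluated on the grid of step ``dt``;
    this equals the continuous convolution at the grid points up to
    spike-time discretization.
    """
    if tau_syn <= 0:
        raise ValueError("tau_syn must be positive")
    if dt <= 0 or dt >= tau_syn:
        raise ValueError("require 0 < dt < tau_syn")
    T = int(round(raster.duration / dt))
    impulses = np.zeros((raster.N, T))
    if raster.n_spikes:
        steps = np.minimum((raster.times / dt).astype(int), T - 1)
        np.add.at(impulses, (raster.neuron_ids, steps), 1.0)
    decay = np.exp(-dt / tau_syn)
    u = lfilter([1.0], [1.0, -decay], impulses, axis=1)
    return FilteredTraces(u, tau_syn, dt)


def simulate_lif(
    current_fn: Callable[[float], np.ndarray],
    params: LIFParams,
    duration: float,
    dt: float,
    N: Optional[int] = None,
    tau_syn: float = 0.02,
    V0: Optional[np.ndarray] = None,
) -> tuple[SpikeRaster, FilteredTraces]:
    """Simulate N independent LIF neurons driven by ``current_fn``.

    ``current_fn(t)`` returns the instantaneous input current vector.
    The membrane follows tau_m dV/dt = (V_leak - V) + R_m I with
    exponential-Euler steps; a spike is recorded when V >= V_th, after
    which V is clamped to V_reset for ``t_ref``.  Spike times are
    resolved on the grid (no interpolation).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    I0 = np.atleast_1d(np.asarray(current_fn(0.0), dtype=float))
    N = I0.size if N is None else N
    th = params.thresholds(N)
    V = np.full(N, params.V_reset, dtype=float) if V0 is None else np.array(V0, float)
    decay = np.exp(-dt / params.tau_m)
    ref_steps = int(round(params.t_ref / dt))
    ref_left = np.zeros(N, dtype=int)

    T = int(round(duration / dt))
    syn_decay = np.exp(-dt / tau_syn)
    u = np.zeros(N)
    u_hist = np.empty((N, T))
    spike_ids: list[np.ndarray] = []
    spike_steps: list[np.ndarray] = []

    for t in range(T):
        I = np.atleast_1d(np.asarray(current_fn(t * dt), dtype=float))
        if not np.all(np.isfinite(I)):
            bad = int(np.flatnonzero(~np.isfinite(I))[0])
            raise FloatingPointError(
                f"non-finite input current for neuron {bad} at step {t} (t={t * dt:.6f}s)"
            )
        V_inf = params.V_leak + params.R_m * I
        V = V_inf + (V - V_inf) * decay
        refractory = ref_left > 0
        V[refractory] = params.V_reset
        ref_left[refractory] -= 1
        fired = (V >= th) & ~refractory
        if np.any(fired):
            idx = np.flatnonzero(fired)
            spike_ids.append(idx)
            spike_steps.append(np.full(idx.size, t))
            V[idx] = params.V_reset
            ref_left[idx] = ref_steps
        u *= syn_decay
        if np.any(fired):
            u[idx] += 1.0
        u_hist[:, t] = u

    if spike_ids:
        ids = np.concatenate(spike_ids)
        times = np.concatenate(spike_steps) * dt
    else:
        ids = np.empty(0, dtype=np.int64)
        times = np.empty(0)
    raster = SpikeRaster(ids, times, N, duration)
    return raster, FilteredTraces(u_hist, tau_syn, dt)


def bin_spikes(raster: SpikeRaster, bin_width: float) -> BinnedRates:
    """Count spikes in consecutive left-closed bins; drop the partial tail."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    B = int(np.floor(raster.duration / bin_width + 1e-9))
    counts = np.zeros((raster.N, B), dtype=np.int64)
    if raster.n_spikes and B > 0:
        bins = (raster.times / bin_width).astype(int)
        keep = bins < B
        np.add.at(counts, (raster.neuron_ids[keep], bins[keep]), 1)
    return BinnedRates(counts, bin_width)


def lif_rate(
    drive: Union[float, np.ndarray],
    params: LIFParams,
    thresholds: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Closed-form stationary firing rate of an LIF neuron vs input current.

    rate = 1 / (t_ref + tau_m * ln((V_inf - V_reset) / (V_inf - V_th)))
    with V_inf = V_leak + R_m * drive, and 0 below rheobase.  Used to
    calibrate gains/biases and to predict activities at evaluation
    points without spiking simulation.
    """
    drive = np.asarray(drive, dtype=float)
    th = params.V_th if thresholds is None else np.asarray(thresholds, float)
    V_inf = params.V_leak + params.R_m * drive
    above = V_inf > th
    rate = np.zeros(np.broadcast(V_inf, th).shape)
    with np.errstate(divide="ignore", over="ignore"):
        num = np.broadcast_to(V_inf - params.V_reset, rate.shape)
        den = np.broadcast_to(V_inf - th, rate.shape)
        log_arg = np.where(above, num / np.where(above, den, 1.0), np.inf)
        isi = params.t_ref + params.tau_m * np.log(log_arg)
        rate = np.where(above, 1.0 / isi, 0.0)
    return rate if rate.ndim else float(rate)
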