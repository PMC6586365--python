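"""Latent target trajectories, encoder matrices and latent dynamics.

Every input of the study is generated here: the step-and-hold fixation
protocol used to probe line-attractor retention, harmonic oscillator
targets, the four-dimensional double-oscillator limit cycle, and the
random encoder matrices ``K`` whose columns define the intrinsic
manifold of a network.

All generators are pure functions of their arguments and a seed:
calling them twice with identical inputs returns bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np


class EncoderScheme(str, Enum):
    """How the rows of an encoder matrix are drawn."""

    uniform_box = "uniform_box"
    unit_sphere_rows = "unit_sphere_rows"
    custom = "custom"


class DynamicsKind(str, Enum):
    integrator = "integrator"
    linear = "linear"
    limit_cycle_4d = "limit_cycle_4d"


@dataclass(frozen=True)
class LatentTrajectory:
    """A latent-variable time course on a uniform time grid.

    Attributes
    ----------
    times : (T,) array, seconds, uniform grid of spacing ``dt``.
    values : (D, T) array, the latent variables x(t).
    fixation_mask : (T,) bool array, True while the latents are
        externally clamped to the target values.
    """

    times: np.ndarray
    values: np.ndarray
    fixation_mask: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        mask = np.asarray(self.fixation_mask, dtype=bool)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("times must be a 1-D grid with at least 2 points")
        dts = np.diff(times)
        if not np.all(dts > 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
            raise ValueError("times must be uniformly spaced")
        if not np.all(np.isfinite(values)):
            raise ValueError("latent values must be finite")
        if values.shape[1] != times.size or mask.shape != times.shape:
            raise ValueError("values/fixation_mask lengths must match times")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "fixation_mask", mask)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def D(self) -> int:
        return int(self.values.shape[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] + self.dt)

    def scaled(self, factor: float) -> "LatentTrajectory":
        """Return a copy with the latent values multiplied by ``factor``."""
        return LatentTrajectory(self.times, self.values * factor, self.fixation_mask)

    def to_txt(self, path: Union[str, Path]) -> None:
        """Write a delimited table: time, x1..xD, fixed_flag."""
        table = np.column_stack(
            [self.times, self.values.T, self.fixation_mask.astype(int)]
        )
        header = "time_s\t" + "\t".join(f"x{i + 1}" for i in range(self.D)) + "\tfixed"
        np.savetxt(path, table, delimiter="\t", header=header, comments="")

    @classmethod
    def from_txt(cls, path: Union[str, Path]) -> "LatentTrajectory":
        table = np.loadtxt(path, delimiter="\t", skiprows=1)
        return cls(table[:, 0], table[:, 1:-1].T, table[:, -1] > 0.5)

    def to_npz(self, path: Union[str, Path]) -> None:
        np.savez(path, times=self.times, values=self.values,
                 fixation_mask=self.fixation_mask)

    @classmethod
    def from_npz(cls, path: Union[str, Path]) -> "LatentTrajectory":
        with np.load(path) as data:
            return cls(data["times"], data["values"], data["fixation_mask"])


@dataclass(frozen=True)
class EncoderMatrix:
    """An N x D encoder matrix K mapping latents to per-neuron currents."""

    entries: np.ndarray
    draw_scheme: EncoderScheme = EncoderScheme.custom

    def __post_init__(self) -> None:
        entries = np.atleast_2d(np.asarray(self.entries, dtype=float))
        if not np.all(np.isfinite(entries)):
            raise ValueError("encoder entries must be finite")
        if self.draw_scheme == EncoderScheme.unit_sphere_rows:
            norms = np.linalg.norm(entries, axis=1)
            if np.any(norms < 1e-12):
                raise ValueError("unit-sphere encoders may not contain zero rows")
        object.__setattr__(self, "entries", entries)

    @property
    def N(self) -> int:
        return int(self.entries.shape[0])

    @property
    def D(self) -> int:
        return int(self.entries.shape[1])


@dataclass(frozen=True)
class DynamicsSpec:
    """Latent dynamics dx/dt = A x (linear) or the 4-D double oscillator."""

    kind: DynamicsKind
    A: np.ndarray = field(default=None)  # type: ignore[assignment]
    omega: float = 0.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == DynamicsKind.integrator:
            A = np.zeros((2, 2)) if self.A is None else np.asarray(self.A, float)
            if np.any(A != 0):
                raise ValueError("integrator dynamics require A = 0")
        elif self.kind == DynamicsKind.linear:
            if self.A is None:
                A = oscillator_matrix(self.omega)
            else:
                A = np.asarray(self.A, float)
            if not np.allclose(A, -A.T, atol=1e-12):
                raise ValueError("linear oscillator matrix must be antisymmetric")
        else:
            A = np.zeros((4, 4)) if self.A is None else np.asarray(self.A, float)
        object.__setattr__(self, "A", A)


def oscillator_matrix(omega: float) -> np.ndarray:
    """Planar rotation generator [[0, -w], [w, 0]] for dx/dt = A x."""
    return np.array([[0.0, -omega], [omega, 0.0]])


def make_step_targets(
    D: int,
    duration: float,
    dt: float,
    period: float = 0.5,
    fix_len: float = 0.1,
    value_range: tuple[float, float] = (-1.0, 1.0),
    seed: int = 0,
) -> LatentTrajectory:
    """Step-and-hold latent targets with a periodic fixation schedule.

    At the start of every ``period`` the D latents are clamped
    (``fixation_mask`` True) to fresh uniform values from
    ``value_range`` for ``fix_len`` seconds; between fixations the held
    value persists as the reference signal, emulating line-attractor
    retention of externally set variables.
    """
    if duration <= 0 or dt <= 0 or period <= 0 or fix_len <= 0:
        raise ValueError("durations must be positive")
    if fix_len > period:
        raise ValueError("fix_len must not exceed period")
    n_periods = duration / period
    if abs(n_periods - round(n_periods)) > 1e-9:
        raise ValueError("duration must be a whole number of periods")
    n_periods = int(round(n_periods))
    rng = np.random.default_rng(seed)
    lo, hi = value_range
    held = rng.uniform(lo, hi, size=(n_periods, D))

    T = int(round(duration / dt))
    times = np.arange(T) * dt
    period_idx = np.minimum((times / period).astype(int), n_periods - 1)
    values = held[period_idx].T
    phase = times - period_idx * period
    mask = phase < fix_len - 1e-12 * period
    # fix_len == period means the clamp never releases
    if abs(fix_len - period) < 1e-12:
        mask = np.ones(T, dtype=bool)
    return LatentTrajectory(times, values, mask)


def make_oscillator_targets(
    f_hz: float,
    duration: float,
    dt: float,
    amplitude: float = 1.0,
    phase: float = 0.0,
) -> LatentTrajectory:
    """Two-dimensional harmonic targets x = amp (cos wt, sin wt).

    Satisfies dx/dt = A x with the antisymmetric planar generator, so it
    is the reference signal for oscillator networks.
    """
    if f_hz < 0:
        raise ValueError("frequency must be non-negative")
    if duration <= 0 or dt <= 0:
        raise ValueError("durations must be positive")
    T = int(round(duration / dt))
    times = np.arange(T) * dt
    w = 2.0 * np.pi * f_hz
    values = amplitude * np.vstack(
        [np.cos(w * times + phase), np.sin(w * times + phase)]
    )
    return LatentTrajectory(times, values, np.zeros(T, dtype=bool))


def draw_encoders(
    scheme: Union[EncoderScheme, str],
    N: int,
    D: int,
    scale: float = 1.0,
    seed: int = 0,
) -> EncoderMatrix:
    """Draw a random N x D encoder matrix.

    ``uniform_box``: entries i.i.d. uniform on [-scale, scale] (the
    reservoir-network convention).  ``unit_sphere_rows``: rows uniform
    on the unit sphere, multiplied by ``scale`` (the tuning-curve
    convention).
    """
    if N < D or D < 1:
        raise ValueError("require N >= D >= 1")
    scheme = EncoderScheme(scheme)
    rng = np.random.default_rng(seed)
    if scheme == EncoderScheme.uniform_box:
        entries = rng.uniform(-scale, scale, size=(N, D))
    elif scheme == EncoderScheme.unit_sphere_rows:
        entries = rng.standard_normal((N, D))
        norms = np.linalg.norm(entries, axis=1, keepdims=True)
        # redraw the (measure-zero) degenerate rows
        while np.any(norms < 1e-12):
            bad = norms[:, 0] < 1e-12
            entries[bad] = rng.standard_normal((bad.sum(), D))
            norms = np.linalg.norm(entries, axis=1, keepdims=True)
        entries = scale * entries / norms
    else:
        raise ValueError("custom encoders must be constructed explicitly")
    return EncoderMatrix(entries, scheme)


def double_oscillator_field(
    x: np.ndarray, omega: float = 2.0 * 2.0 * np.pi, alpha: float = 0.2
) -> np.ndarray:
    """Vector field of the 4-D double oscillator.

    The first latent pair rotates at angular frequency ``omega``, the
    second at ``2*omega``; a radial term ``alpha * (1 - r^2)`` per pair
    makes the unit-amplitude cycle attracting for ``alpha > 0``.
    Accepts a 4-vector or an (M, 4) batch of points.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = np.atleast_2d(x)
    if pts.shape[1] != 4:
        raise ValueError("the double oscillator is four-dimensional")
    x1, x2, x3, x4 = pts.T
    r1 = alpha * (1.0 - (x1**2 + x2**2))
    r2 = alpha * (1.0 - (x3**2 + x4**2))
    out = np.column_stack(
        [
            omega * x2 + r1 * x1,
            -omega * x1 + r1 * x2,
            2.0 * omega * x4 + r2 * x3,
            -2.0 * omega * x3 + r2 * x4,
        ]
    )
    return out[0] if single else out


def limit_cycle_reference(
    omega: float,
    alpha: float,
    x0: np.ndarray,
    duration: float,
    dt: float,
) -> LatentTrajectory:
    """Integrate the 4-D double oscillator with fixed-step RK4.

    The fixed step matches the spiking-simulation grid so reference and
    decoded trajectories share time axes.  Raises if the trajectory
    diverges (it should not: amplitude 1 is attracting for alpha > 0).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("durations must be positive")
    if dt * max(omega, 1e-12) > 0.5:
        raise ValueError("dt too coarse for the requested frequency")
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (4,):
        raise ValueError("x0 must be a 4-vector")
    T = int(round(duration / dt))
    times = np.arange(T) * dt
    values = np.empty((4, T))
    x = x0.copy()
    f = double_oscillator_field
    for t in range(T):
        values[:, t] = x
        k1 = f(x, omega, alpha)
        k2 = f(x + 0.5 * dt * k1, omega, alpha)
        k3 = f(x + 0.5 * dt * k2, omega, alpha)
        k4 = f(x + dt * k3, omega, alpha)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if np.linalg.norm(x) > 1e3:
            raise FloatingPointError(f"limit-cycle integration diverged at t={t * dt:.4f}s")
    return LatentTrajectory(times, values, np.zeros(T, dtype=bool))
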