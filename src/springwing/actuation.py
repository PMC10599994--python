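"""Muscle forcing: synchronous sinusoid, asynchronous feedback, and the
K_r-weighted antagonistic pair.

Synchronous (neurogenic) forcing is a pure sinusoid Fs sin(2 pi fs t).
Asynchronous forcing is delayed-stretch-activation feedback: the muscle
strain rate (wing velocity referred through the transmission,
strain_rate = phid/(L T)) is convolved with the negated DSA kernel,

    F_async(t) = mu * Fa/(L T) * (-g * phid)(t),

so that a stretch (negative strain rate in the shortening-positive
convention) produces a delayed positive tension.  The two are combined per
muscle with the interpolation factor K_r in [0, 1],

    F = K_r F_sync + (1 - K_r) F_async,

for an antagonistic pair: the downstroke muscle sees the wing velocity
as-is with phase offset 0, the upstroke muscle sees the negated velocity
with phase offset pi, and each muscle is saturated to tension-only (>= 0)
before the pair is summed with opposite signs.  Because the two raw forces
are exact negatives, the clipped pair sums to the signed single-muscle
expression; in particular K_r = 1 yields exactly Fs sin(2 pi fs t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from springwing.kernel import DiscreteFilter, DSAKernel, discretize

#: Per-muscle sinusoid phase offsets (rad): downstroke 0, upstroke pi.
THETA_DOWN = 0.0
THETA_UP = math.pi


@dataclass
class ForcingConfig:
    """Combined-forcing parameters for one antagonistic muscle pair."""

    Kr: float               # interpolation factor in [0, 1]
    Fs: float               # synchronous amplitude, N
    fs: float               # synchronous frequency, Hz
    mu: float               # asynchronous scaling factor
    Fa: float               # DSA force magnitude, N
    kernel: DSAKernel
    L: float                # muscle resting length, m
    T: float                # transmission ratio, rad/m
    theta0_down: float = THETA_DOWN
    theta0_up: float = THETA_UP

    def __post_init__(self) -> None:
        if not (0.0 <= self.Kr <= 1.0):
            raise ValueError(f"Kr must lie in [0, 1], got {self.Kr}")
        if self.Fa < 0 or self.Fs < 0 or self.mu < 0:
            raise ValueError("Fs, Fa and mu must be non-negative")

    @property
    def async_gain(self) -> float:
        """Feedback gain mu*Fa/(L*T) multiplying the convolution (N s/rad)."""
        return self.mu * self.Fa / (self.L * self.T)


class FilterState:
    """Causal ring buffer of wing angular velocities for FIR evaluation.

    The buffer holds the most recent ``len(filter)`` samples at the control
    rate; :meth:`push` appends the current velocity, :meth:`convolve`
    evaluates dt * sum_j g[j] * phid[n-j] (units rad/s after the dt
    scaling, i.e. the continuous convolution (g * phid)(t)).
    """

    def __init__(self, filt: DiscreteFilter):
        self.filter = filt
        self._buf = np.zeros(filt.truncation_index)
        self._pos = 0  # index of the most recent sample

    def reset(self) -> None:
        self._buf[:] = 0.0
        self._pos = 0

    def push(self, phid: float) -> None:
        self._pos = (self._pos + 1) % len(self._buf)
        self._buf[self._pos] = phid

    def convolve(self) -> float:
        c = self.filter.coefficients
        n = len(c)
        # history ordered most-recent-first
        idx = (self._pos - np.arange(n)) % n
        return float(c @ self._buf[idx]) * self.filter.dt

    def check_dt(self, dt: float) -> None:
        if not math.isclose(self.filter.dt, dt, rel_tol=1e-12):
            raise ValueError(
                f"filter dt={self.filter.dt} does not match control dt={dt}"
            )


def synchronous_force(t, Fs: float, fs: float, theta0: float = 0.0):
    """Neurogenic sinusoid Fs sin(2 pi fs t + theta0) (N)."""
    return Fs * np.sin(2.0 * math.pi * fs * np.asarray(t, dtype=float) + theta0)


def asynchronous_force(
    state: FilterState,
    mu: float,
    Fa: float,
    L: float,
    T: float,
    dt: float | None = None,
) -> float:
    """DSA feedback force mu*Fa/(L T) * (-g * phid)(t) from buffered history."""
    if dt is not None:
        state.check_dt(dt)
    return -mu * Fa / (L * T) * state.convolve()


def _tension(f: float) -> float:
    """Tension-only saturation: muscles cannot push."""
    return f if f > 0.0 else 0.0


def muscle_pair_force(t: float, state: FilterState, config: ForcingConfig):
    """Net force of the antagonistic pair and its per-muscle components.

    Returns ``(net, F_down, F_up)`` where ``F_down``/``F_up`` are the
    clipped (tension-only) per-muscle forces and ``net = F_down - F_up``.
    Clipping is applied to each muscle's combined K_r-weighted force.
    """
    conv = state.convolve()  # (g * phid)(t)
    sync_down = config.Fs * math.sin(
        2.0 * math.pi * config.fs * t + config.theta0_down
    )
    gain = config.async_gain
    # downstroke strain rate = phid/(LT); upstroke sees the negated velocity
    raw_down = config.Kr * sync_down + (1.0 - config.Kr) * (-gain * conv)
    raw_up = -raw_down  # antagonist: both sine phase and velocity negated
    f_down = _tension(raw_down)
    f_up = _tension(raw_up)
    return f_down - f_up, f_down, f_up


def make_filter_state(kernel: DSAKernel, dt: float) -> FilterState:
    """Discretize a kernel at the control rate and wrap it in a FilterState."""
    return FilterState(discretize(kernel, dt))


def net_combined_force(t, conv, config: ForcingConfig):
    """Vectorized net pair force given precomputed convolution samples.

    Identical to summing the clipped antagonistic pair (the raw per-muscle
    forces are exact negatives, so clip(x) - clip(-x) = x).
    """
    sync = synchronous_force(t, config.Fs, config.fs, config.theta0_down)
    return config.Kr * sync - (1.0 - config.Kr) * config.async_gain * np.asarray(conv)
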