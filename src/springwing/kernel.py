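"""Reduced delayed-stretch-activation (DSA) kernel.

Asynchronous flight muscle responds to an imposed stretch with a time-lagged
rise and fall of tension.  The reduced model keeps only the rising rate
constant ``r3`` and the slow decay ``r4`` of the classic sum-of-exponentials
step response, giving the velocity impulse response

    g(t) = (1/g0) * (-exp(-r3 t) + exp(-r4 t)),     t >= 0,

normalized by its area g0 = 1/r4 - 1/r3 so that g integrates to one.  The
kernel peaks at the time-to-peak

    t0 = ln(r3/r4) / (r3 - r4),

the single timescale of the reduced model.  Holding the ratio
kappa = r4/r3 fixed (0.62 for Manduca sexta flight muscle) makes t0 the only
free parameter: t0 = ln(kappa) / (r3 (kappa - 1)), i.e. t0 = 1.258/r3 at
kappa = 0.62.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MANDUCA_KAPPA = 0.62
"""Ratio r4/r3 fitted for M. sexta flight muscle; held constant in sweeps."""

# Relative rate difference below which the confluent (r3 == r4) limit
# t * exp(-r t) is used instead of the two-exponential closed form.
_CONFLUENT_TOL = 1e-9


def _validate_rates(r3: float, r4: float) -> None:
    if not (r3 > 0.0 and r4 > 0.0):
        raise ValueError(f"rate constants must be positive, got r3={r3}, r4={r4}")


def _is_confluent(r3: float, r4: float) -> bool:
    return abs(r3 - r4) <= _CONFLUENT_TOL * max(r3, r4)


def time_to_peak(r3: float, r4: float) -> float:
    """Time at which the unnormalized kernel -e^(-r3 t) + e^(-r4 t) peaks.

    Continuous at r3 == r4, where the limit is 1/r3.
    """
    _validate_rates(r3, r4)
    if _is_confluent(r3, r4):
        return 1.0 / r3
    return float(np.log(r3 / r4) / (r3 - r4))


def kernel_area(r3: float, r4: float) -> float:
    """Analytic area under the unnormalized kernel, g0 = 1/r4 - 1/r3.

    This is the normalization constant of the kernel.  The analytic value is
    used throughout; it is not mixed with numerical quadrature.  In the
    confluent limit the area of t*exp(-r t) is 1/r^2.
    """
    _validate_rates(r3, r4)
    if _is_confluent(r3, r4):
        return 1.0 / (r3 * r3)
    return 1.0 / r4 - 1.0 / r3


@dataclass(frozen=True)
class DSAKernel:
    """Two-rate stretch-activation impulse response.

    Attributes
    ----------
    r3, r4 : float
        Rising and slow-decay rate constants (1/s).  ``r4 < r3`` gives a
        non-negative kernel.
    kappa : float
        Ratio r4/r3.
    t0 : float
        Time-to-peak ln(r3/r4)/(r3 - r4) (s).
    g0 : float
        Area under the unnormalized kernel (s); the normalization constant.
    """

    r3: float
    r4: float
    kappa: float = field(init=False)
    t0: float = field(init=False)
    g0: float = field(init=False)

    def __post_init__(self) -> None:
        _validate_rates(self.r3, self.r4)
        object.__setattr__(self, "kappa", self.r4 / self.r3)
        object.__setattr__(self, "t0", time_to_peak(self.r3, self.r4))
        object.__setattr__(self, "g0", kernel_area(self.r3, self.r4))

    def __call__(self, times) -> np.ndarray:
        return evaluate_kernel(self, times)

    def frequency_response(self, f) -> np.ndarray:
        """Analytic Fourier transform G(j 2 pi f) of the normalized kernel.

        G(jw) = (1/g0) * (1/(r4 + jw) - 1/(r3 + jw)).  Used as the
        closed-form oracle for the discrete FIR filter and for linear
        work-loop response.
        """
        w = 2.0 * np.pi * np.asarray(f, dtype=float)
        if _is_confluent(self.r3, self.r4):
            # transform of t e^{-rt} is 1/(r+jw)^2
            return (1.0 / self.g0) / (self.r3 + 1j * w) ** 2
        return (1.0 / self.g0) * (1.0 / (self.r4 + 1j * w) - 1.0 / (self.r3 + 1j * w))


def evaluate_kernel(kernel: DSAKernel, times) -> np.ndarray:
    """Evaluate the normalized kernel g(t) on non-negative times (units 1/s)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel is causal; times must be non-negative")
    if _is_confluent(kernel.r3, kernel.r4):
        return (1.0 / kernel.g0) * t * np.exp(-kernel.r3 * t)
    return (1.0 / kernel.g0) * (-np.exp(-kernel.r3 * t) + np.exp(-kernel.r4 * t))


def rates_from_t0(t0: float, kappa: float = MANDUCA_KAPPA) -> tuple[float, float]:
    """Invert the time-to-peak relation at fixed rate ratio kappa = r4/r3.

    r3 = ln(kappa) / (t0 (kappa - 1)), r4 = kappa * r3.  The kappa -> 1
    limit r3 = 1/t0 is handled continuously.
    """
    if t0 <= 0:
        raise ValueError(f"t0 must be positive, got {t0}")
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if abs(kappa - 1.0) <= _CONFLUENT_TOL:
        r3 = 1.0 / t0
    else:
        r3 = float(np.log(kappa) / (t0 * (kappa - 1.0)))
    return r3, kappa * r3


def t0_coefficient(kappa: float) -> float:
    """Coefficient c in t0 = c/r3 at fixed kappa: c = ln(kappa)/(kappa - 1)."""
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if abs(kappa - 1.0) <= _CONFLUENT_TOL:
        return 1.0
    return float(np.log(kappa) / (kappa - 1.0))


@dataclass(frozen=True)
class DiscreteFilter:
    """Sampled kernel for causal discrete (FIR) convolution.

    ``coefficients`` are the kernel values g(n dt) for n = 0..truncation-1;
    a discrete convolution of the coefficients with an input history, scaled
    by ``dt``, approximates the continuous convolution integral.
    """

    coefficients: np.ndarray
    dt: float
    truncation_index: int

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.truncation_index:
            raise ValueError("coefficient count must equal truncation_index")

    def apply(self, signal) -> np.ndarray:
        """Causal convolution of a full input signal with the filter.

        Returns an output of the same length: out[n] = dt * sum_j c[j] x[n-j].
        A unit discrete impulse (1/dt at n = 0) reproduces the coefficients.
        """
        x = np.asarray(signal, dtype=float)
        full = np.convolve(x, self.coefficients)[: len(x)]
        return full * self.dt

    @property
    def support(self) -> float:
        """Temporal support of the truncated kernel (s)."""
        return self.truncation_index * self.dt

    def tail_mass(self, kernel: DSAKernel) -> float:
        """Analytic mass of the truncated tail beyond the filter support."""
        T = self.support
        if _is_confluent(kernel.r3, kernel.r4):
            r = kernel.r3
            return float((T + 1.0 / r) * np.exp(-r * T) / (r * kernel.g0))
        return float(
            (np.exp(-kernel.r4 * T) / kernel.r4 - np.exp(-kernel.r3 * T) / kernel.r3)
            / kernel.g0
        )


def discretize(kernel: DSAKernel, dt: float) -> DiscreteFilter:
    """Sample the kernel at t = 0, dt, 2dt, ... and truncate the tail.

    Truncation is at the first sample past the peak where the sampled kernel
    falls below 1% of its maximum (the below-1% region near t = 0 is not a
    valid truncation point).  Raises if dt cannot resolve the kernel peak.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if dt >= kernel.t0:
        raise ValueError(
            f"dt={dt} >= t0={kernel.t0:.6g}: kernel unresolvable at this rate"
        )
    if dt > kernel.t0 / 10.0:
        warnings.warn(
            f"dt={dt} > t0/10={kernel.t0 / 10:.3g}; kernel coarsely sampled",
            stacklevel=2,
        )
    # generous upper bound on support: peak + tail decay to 1e-4 of max
    n_max = int(np.ceil((kernel.t0 + np.log(1e4) / kernel.r4) / dt)) + 2
    t = np.arange(n_max) * dt
    g = evaluate_kernel(kernel, t)
    peak_idx = int(np.argmax(g))
    gmax = g[peak_idx]
    below = np.nonzero(g[peak_idx:] < 0.01 * gmax)[0]
    if below.size == 0:  # pragma: no cover - n_max bound guarantees a crossing
        raise RuntimeError("kernel tail did not fall below 1% of max in bound")
    trunc = peak_idx + int(below[0])
    return DiscreteFilter(coefficients=g[:trunc].copy(), dt=dt, truncation_index=trunc)


def export_sampled_kernel(filt: DiscreteFilter, path) -> None:
    """Write the sampled kernel as a two-column CSV table (t, g)."""
    t = np.arange(filt.truncation_index) * filt.dt
    arr = np.column_stack([t, filt.coefficients])
    np.savetxt(path, arr, delimiter=",", header="t_s,g_per_s", comments="")
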