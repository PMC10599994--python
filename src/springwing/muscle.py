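"""Muscle-physiology analysis: stretch-hold-release-hold traces.

A tetanically activated muscle is stretched by the in-vivo strain amplitude
at the in-vivo strain rate, held, released, and held again while stress is
recorded.  Delayed stretch activation (DSA) appears as a delayed rise of
stress after the stretch.  The classic description of the post-stretch
force is a sum of three exponentials,

    F_step(t) = K2 e^(-r2 t) + K3 (1 - e^(-r3 t)) + K4 e^(-r4 t) + c,

with a fast viscoelastic decay (r2), the delayed tension rise (r3), a slow
decay (r4), and a passive offset c.  The reduced two-rate kernel drops the
viscoelastic terms and keeps only the rise-and-fall (r3, r4) that matter
for self-excitation.

Sign convention throughout: strain and force are positive in the
*shortening* direction, so a stretch is a negative strain ramp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from springwing.kernel import DSAKernel, evaluate_kernel, t0_coefficient

__all__ = [
    "StrainProtocol",
    "StepTrace",
    "StepResponseFit",
    "DSAMeasurement",
    "DSASummary",
    "MuscleGeometry",
    "manduca_reference_fit",
    "synthesize_trace",
    "fit_step_response",
    "fit_reduced_kernel",
    "dsa_magnitude",
    "quasi_static_kr",
    "iir_scale_factor",
    "work_loop_power",
    "cross_sectional_area",
]


@dataclass(frozen=True)
class StrainProtocol:
    """Stretch-hold-release-hold strain trajectory.

    ``epsilon0`` is the peak strain magnitude (dimensionless); the ramp
    rate is the peak in-vivo strain rate epsilon_dot0 = 2 pi f epsilon0
    for wingbeat frequency f.
    """

    epsilon0: float = 0.045
    f: float = 25.0                     # Hz, reference wingbeat frequency
    hold_pre: float = 0.150             # s
    hold_post: float = 0.150            # s
    hold_final: float = 0.150           # s
    stimulation_frequency: float = 150.0  # Hz, metadata
    epsilon_dot0: float = field(init=False)

    def __post_init__(self) -> None:
        if self.epsilon0 <= 0 or self.f <= 0:
            raise ValueError("epsilon0 and f must be positive")
        object.__setattr__(
            self, "epsilon_dot0", 2.0 * math.pi * self.f * self.epsilon0
        )

    @property
    def ramp_duration(self) -> float:
        """Duration of the stretch (and release) ramp (s)."""
        return self.epsilon0 / self.epsilon_dot0

    def strain(self, t: np.ndarray) -> np.ndarray:
        """Strain trajectory (shortening-positive; stretch goes negative)."""
        t = np.asarray(t, dtype=float)
        t1 = self.hold_pre
        t2 = t1 + self.ramp_duration
        t3 = t2 + self.hold_post
        t4 = t3 + self.ramp_duration
        eps = np.zeros_like(t)
        ramp = (t >= t1) & (t < t2)
        eps[ramp] = -self.epsilon_dot0 * (t[ramp] - t1)
        eps[(t >= t2) & (t < t3)] = -self.epsilon0
        rel = (t >= t3) & (t < t4)
        eps[rel] = -self.epsilon0 + self.epsilon_dot0 * (t[rel] - t3)
        return eps

    @property
    def stretch_end(self) -> float:
        return self.hold_pre + self.ramp_duration

    @property
    def release_start(self) -> float:
        return self.stretch_end + self.hold_post

    @property
    def total_duration(self) -> float:
        return self.release_start + self.ramp_duration + self.hold_final


@dataclass
class StepTrace:
    """Recorded (or synthesized) time/stress/strain table.

    Stress in kN/m^2 (or normalized to tetanus); shortening-positive.
    """

    time: np.ndarray
    stress: np.ndarray
    strain: np.ndarray
    shortening_positive: bool = True

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if not (len(self.time) == len(self.stress) == len(self.strain)):
            raise ValueError("time, stress and strain must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def stretch_end_index(self) -> int:
        """First sample at which the stretch ramp has completed.

        Detected from the strain channel: the first index where strain
        reaches its minimum (most-stretched) plateau.
        """
        smin = np.min(self.strain)
        if smin >= 0.0:
            raise ValueError("trace contains no stretch (strain never negative)")
        return int(np.argmax(self.strain <= smin + 1e-12))

    def release_start_index(self) -> int:
        """Last sample of the post-stretch hold."""
        i0 = self.stretch_end_index()
        smin = np.min(self.strain)
        after = self.strain[i0:]
        rising = np.nonzero(after > smin + 1e-12)[0]
        return i0 + int(rising[0]) - 1 if rising.size else len(self.strain) - 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.time, "stress_kNm2": self.stress, "strain": self.strain}
        )

    @classmethod
    def from_frame(cls, df) -> "StepTrace":
        return cls(
            time=df["time_s"].to_numpy(),
            stress=df["stress_kNm2"].to_numpy(),
            strain=df["strain"].to_numpy(),
        )


def step_response(t, K2, K3, K4, r2, r3, r4, c):
    """Seven-parameter sum-of-exponentials post-stretch force."""
    t = np.asarray(t, dtype=float)
    return (
        K2 * np.exp(-r2 * t)
        + K3 * (1.0 - np.exp(-r3 * t))
        + K4 * np.exp(-r4 * t)
        + c
    )


@dataclass
class StepResponseFit:
    """Fitted parameters of the seven-parameter step response."""

    K2: float
    K3: float
    K4: float
    r2: float
    r3: float
    r4: float
    c: float
    rmse: float = float("nan")
    n_points: int = 0
    converged: bool = True
    attempted_starts: int = 1

    def curve(self, t) -> np.ndarray:
        return step_response(t, self.K2, self.K3, self.K4, self.r2, self.r3, self.r4, self.c)

    def as_dict(self) -> dict:
        return {
            "K2": self.K2, "K3": self.K3, "K4": self.K4,
            "r2": self.r2, "r3": self.r3, "r4": self.r4, "c": self.c,
        }


@dataclass(frozen=True)
class DSAMeasurement:
    """Trough-to-peak DSA magnitude of one trace."""

    magnitude: float        # stress units
    delay_to_peak: float    # s from stretch completion
    has_dsa: bool


@dataclass(frozen=True)
class DSASummary:
    """Quasi-static summary of one muscle's DSA response."""

    Fa: float               # DSA magnitude, stress units
    Ftet: float             # tetanic stress
    twitch: float
    delay_to_peak: float    # s
    Kr_tilde: float
    iir_scalar: float = 1.0

    def __post_init__(self) -> None:
        if min(self.Fa, self.Ftet, self.twitch) < 0:
            raise ValueError("stresses must be non-negative")


@dataclass(frozen=True)
class MuscleGeometry:
    """Muscle dimensions; cross-section from mass/(density * length)."""

    L: float            # resting length, m
    mass: float         # kg
    density: float = 1000.0  # kg/m^3

    @property
    def cross_sectional_area(self) -> float:
        return cross_sectional_area(self.mass, self.L, self.density)


def cross_sectional_area(mass: float, length: float, density: float) -> float:
    """Cross-sectional area = mass / (density * length)."""
    if min(mass, length, density) <= 0:
        raise ValueError("mass, length and density must be positive")
    return mass / (density * length)


def quasi_static_kr(Ftet: float, Fa: float) -> float:
    """Quasi-static interpolation factor K_r~ = Ftet / (Fa + Ftet).

    1 when there is no stretch activation; approaches 0 when DSA force far
    exceeds the neurogenic tetanic force.
    """
    if Ftet <= 0:
        raise ValueError("Ftet must be positive")
    if Fa < 0:
        raise ValueError("Fa must be non-negative")
    return Ftet / (Fa + Ftet)


# ---------------------------------------------------------------------------
# Synthesis


def manduca_reference_fit(
    Ftet: float = 203.0,
    Fa: float = 32.1,
    r3: float = 36.39,
    r4: float = 22.80,
    K2: float = 0.0,
    r2: float = 300.0,
) -> StepResponseFit:
    """Reference step-response parameters at the M. sexta mean stresses.

    Amplitudes are chosen so the post-stretch hold rises by exactly ``Fa``
    above its trough on a tetanic plateau ``Ftet`` (kN/m^2), with the
    reduced-kernel shape K3 = K4 (pure rise-and-fall) plus an optional
    viscoelastic transient K2 e^(-r2 t).
    """
    from springwing.kernel import time_to_peak

    t0 = time_to_peak(r3, r4)
    hump = math.exp(-r4 * t0) - math.exp(-r3 * t0)
    A = Fa / hump
    return StepResponseFit(K2=K2, K3=A, K4=A, r2=r2, r3=r3, r4=r4, c=Ftet - A)


def synthesize_trace(
    protocol: StrainProtocol,
    true_fit: StepResponseFit,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    dt: float = 1e-4,
    sensor_noise: float = 0.0,
    release_factor: float = 0.4,
) -> StepTrace:
    """Generate a stretch-hold-release-hold trace from known parameters.

    The post-stretch hold reproduces the seven-parameter step response
    exactly in the noiseless case; the pre-stretch plateau sits at the
    response's asymptote K3 + c (the tetanic level), the stretch ramp
    interpolates linearly up to the viscoelastic peak F_step(0), and the
    release is modelled as a partial mirrored viscoelastic drop (scaled by
    ``release_factor``) with no shortening deactivation.

    Noise is multiplicative Gaussian on stress (``noise_sigma`` relative)
    plus optional low-pass-filtered additive sensor noise; deterministic
    given ``seed``.
    """
    n = int(round(protocol.total_duration / dt)) + 1
    t = np.arange(n) * dt
    strain = protocol.strain(t)
    stress = np.empty(n)
    plateau = true_fit.K3 + true_fit.c
    t1, t3 = protocol.hold_pre, protocol.release_start
    t4 = t3 + protocol.ramp_duration
    # reference the step response to the first grid sample at/after the end
    # of the stretch ramp, so the sampled hold reproduces it exactly
    t2 = dt * math.ceil(protocol.stretch_end / dt - 1e-9)
    f0 = step_response(0.0, **true_fit.as_dict())
    pre = t < t1
    ramp = (t >= t1) & (t < t2)
    hold = (t >= t2) & (t < t3)
    stress[pre] = plateau
    stress[ramp] = plateau + (f0 - plateau) * (t[ramp] - t1) / (t2 - t1)
    stress[hold] = step_response(t[hold] - t2, **true_fit.as_dict())
    # release: partial mirrored viscoelastic drop recovering to the plateau
    v_end = step_response(t3 - t2, **true_fit.as_dict())
    rel = (t >= t3) & (t < t4)
    drop = release_factor * (f0 - plateau)
    stress[rel] = v_end - drop * (t[rel] - t3) / (t4 - t3)
    after = t >= t4
    tau = t[after] - t4
    stress[after] = plateau + (v_end - drop - plateau) * np.exp(-true_fit.r2 * tau)
    if noise_sigma > 0.0 or sensor_noise > 0.0:
        rng = np.random.default_rng(seed)
        if noise_sigma > 0.0:
            stress = stress * (1.0 + noise_sigma * rng.standard_normal(n))
        if sensor_noise > 0.0:
            raw = sensor_noise * rng.standard_normal(n)
            # single-pole low-pass at ~100 Hz to emulate smooth sensor drift
            alpha = math.exp(-2.0 * math.pi * 100.0 * dt)
            filt = np.empty(n)
            acc = 0.0
            for i in range(n):
                acc = alpha * acc + (1.0 - alpha) * raw[i]
                filt[i] = acc
            stress = stress + filt
    return StepTrace(time=t, stress=stress, strain=strain)


# ---------------------------------------------------------------------------
# Fitting


def _post_stretch_window(trace: StepTrace):
    i0 = trace.stretch_end_index()
    i1 = trace.release_start_index()
    if i1 - i0 < 8:
        raise ValueError("post-stretch hold too short to fit")
    tau = trace.time[i0 : i1 + 1] - trace.time[i0]
    y = trace.stress[i0 : i1 + 1]
    return tau, y, i0, i1


def dsa_magnitude(trace: StepTrace) -> DSAMeasurement:
    """Trough-to-peak stress rise of the post-stretch hold.

    The DSA magnitude is the difference between the lowest stress
    immediately after the stretch (the viscoelastic minimum) and the peak
    stress later in the plateau phase, with the delay measured from stretch
    completion to that peak.  A monotonically decaying hold is reported as
    magnitude 0 with ``has_dsa=False``.
    """
    tau, y, i0, _ = _post_stretch_window(trace)
    itr = _first_trough(y)
    if itr is None:
        return DSAMeasurement(0.0, float("nan"), False)
    seg = y[itr:]
    ipk = itr + int(np.argmax(seg))
    if ipk == itr or y[ipk] - y[itr] <= 0.0:
        return DSAMeasurement(0.0, float("nan"), False)
    # guard: peak at the very end of the hold means no identifiable peak
    if ipk == len(y) - 1 and seg[-1] > seg[-2]:
        raise ValueError("stress still rising at end of hold: no identifiable peak")
    return DSAMeasurement(float(y[ipk] - y[itr]), float(tau[ipk]), True)


def _first_trough(y: np.ndarray) -> int | None:
    """Index of the first local minimum (the post-stretch viscoelastic
    trough), or the start if the trace rises immediately; None if the
    stress only decays."""
    d = np.diff(y)
    if d.size == 0:
        return None
    if d[0] > 0:
        return 0
    sign_change = np.nonzero((d[:-1] < 0) & (d[1:] >= 0))[0]
    if sign_change.size == 0:
        return None
    return int(sign_change[0]) + 1


def _initial_t0(tau, y) -> float:
    itr = _first_trough(y)
    if itr is None:
        itr = 0
    ipk = itr + int(np.argmax(y[itr:]))
    t0_hat = tau[ipk]
    if not (t0_hat > 0):
        t0_hat = tau[-1] / 4.0
    return float(t0_hat)


def fit_step_response(
    trace: StepTrace,
    fit_window: tuple[float, float] | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> StepResponseFit:
    """Nonlinear least-squares fit of the seven-parameter step response.

    The window defaults to the full post-stretch hold (from completion of
    the stretch ramp to the release).  Multi-start initialization: the
    viscoelastic rate starts at 10/ramp-duration, the rise at
    1.258/t0_hat with t0_hat the observed trough-to-peak delay, and the
    slow decay at 0.62 of the rise; additional starts jitter these, since
    the r2/r4 symmetry makes single-start fits fragile.
    """
    tau, y, i0, i1 = _post_stretch_window(trace)
    if fit_window is not None:
        lo, hi = fit_window
        t_abs = trace.time[i0 : i1 + 1]
        m = (t_abs >= lo) & (t_abs <= hi)
        if m.sum() < 8:
            raise ValueError("fit window excludes the force plateau")
        tau, y = tau[m] - tau[m][0], y[m]
    ramp = _ramp_duration(trace)
    t0_hat = _initial_t0(tau, y)
    r2_0 = 10.0 / ramp
    r3_0 = t0_coefficient(0.62) / t0_hat
    r4_0 = 0.62 * r3_0
    rng = np.random.default_rng(seed)
    starts = [(r2_0, r3_0, r4_0), (3.0 / ramp, r3_0, r4_0),
              (r2_0, 2.0 * r3_0, 0.3 * r3_0)]
    while len(starts) < max(n_starts, 3):
        j = rng.lognormal(0.0, 0.5, size=3)
        starts.append((r2_0 * j[0], r3_0 * j[1], r4_0 * j[2]))
    best = None
    tried = 0
    for r2s, r3s, r4s in starts[:max(n_starts, 3)]:
        tried += 1
        sol = _varpro_fit(tau, y, [r2s, r3s, r4s], _design_step)
        if sol is None:
            continue
        ssr, rates, amps = sol
        if best is None or ssr < best[0]:
            best = (ssr, rates, amps)
    if best is None:
        return StepResponseFit(*([float("nan")] * 7), rmse=float("nan"),
                               n_points=len(y), converged=False,
                               attempted_starts=tried)
    ssr, rates, amps = best
    K2, K3, K4, r2, r3, r4, c = _canonicalize_step(rates, amps)
    return StepResponseFit(
        K2=K2, K3=K3, K4=K4, r2=r2, r3=r3, r4=r4, c=c,
        rmse=math.sqrt(ssr / len(y)),
        n_points=len(y), converged=True, attempted_starts=tried,
    )


def _canonicalize_step(rates, amps):
    """Map a fitted exponential triple to the physiological labelling.

    The step-response model is invariant under relabelling its three
    exponentials; the canonical form assigns the fastest rate to the
    viscoelastic decay r2, the middle to the tension rise r3 (with
    K3 >= 0 by sign convention of the 1 - e^(-r3 t) term), and the
    slowest to r4.
    """
    r2, r3, r4 = rates
    K2, K3, K4, c = amps
    # exponential form F = a + sum b_i exp(-rho_i t)
    rho = np.array([r2, r3, r4], dtype=float)
    b = np.array([K2, -K3, K4], dtype=float)
    a = c + K3
    neg = np.nonzero(b < 0)[0]
    if len(neg) >= 1:
        # the tension rise is the negative-coefficient exponential (the
        # largest one if noise produced several)
        i3 = neg[np.argmax(-b[neg])]
        rest = sorted((i for i in range(3) if i != i3),
                      key=lambda i: -rho[i])
        order = [rest[0], i3, rest[1]]
    else:
        order = list(np.argsort(rho)[::-1])
    rho, b = rho[order], b[order]
    K2n, K3n, K4n = b[0], -b[1], b[2]
    cn = a - K3n
    return (float(K2n), float(K3n), float(K4n),
            float(rho[0]), float(rho[1]), float(rho[2]), float(cn))


def _design_step(tau: np.ndarray, rates) -> np.ndarray:
    """Linear design matrix of the step response at fixed rates."""
    r2, r3, r4 = rates
    return np.column_stack(
        [np.exp(-r2 * tau), 1.0 - np.exp(-r3 * tau), np.exp(-r4 * tau),
         np.ones_like(tau)]
    )


def _design_reduced(tau: np.ndarray, rates) -> np.ndarray:
    r3, r4 = rates
    return np.column_stack(
        [np.exp(-r4 * tau) - np.exp(-r3 * tau), np.ones_like(tau)]
    )


def _varpro_fit(tau, y, rates0, design):
    """Variable-projection fit: optimize rates, solve amplitudes linearly.

    Sums of exponentials are notoriously ill-conditioned in a joint fit
    (near-degenerate rate pairs trade off against unbounded amplitudes);
    projecting out the linear amplitudes leaves a low-dimensional, much
    better-behaved problem in the log-rates.
    """
    from scipy.optimize import least_squares

    def resid(log_r):
        A = design(tau, np.exp(log_r))
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return A @ coef - y

    # rates bounded to the resolvable band: slower than ~1/window,
    # faster only up to a few samples' decay time
    dt = float(tau[1] - tau[0]) if len(tau) > 1 else 1e-4
    lo = math.log(0.05 / max(tau[-1], 1e-9))
    hi = math.log(0.5 / dt)
    x0 = np.clip(np.log(np.asarray(rates0, dtype=float)), lo + 1e-9, hi - 1e-9)
    try:
        out = least_squares(
            resid, x0, bounds=(lo, hi), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=4000,
        )
    except (ValueError, np.linalg.LinAlgError):
        return None
    rates = np.exp(out.x)
    A = design(tau, rates)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = A @ coef - y
    return float(r @ r), rates, coef


def _ramp_duration(trace: StepTrace) -> float:
    i0 = trace.stretch_end_index()
    neg = np.nonzero(trace.strain[: i0 + 1] < -1e-12)[0]
    start = int(neg[0]) - 1 if neg.size else 0
    return max(trace.time[i0] - trace.time[start], trace.dt)


def _reduced_model(tau, A, r3, r4, base):
    return base + A * (np.exp(-r4 * tau) - np.exp(-r3 * tau))


def fit_reduced_kernel(
    trace: StepTrace, n_starts: int = 5, seed: int = 0
) -> tuple[DSAKernel, StepResponseFit]:
    """Two-rate (r3, r4) fit of the post-stretch rise and fall.

    The initial viscoelastic transient is excluded by starting the window
    at the post-stretch stress minimum; time is still referenced to the
    completion of the stretch ramp, so the recovered rates correspond to
    the kernel of the underlying impulse response.  Returns the kernel and
    a fit record (amplitude stored in K4, offset in c).
    """
    tau, y, _, _ = _post_stretch_window(trace)
    itr = _first_trough(y)
    if itr is None:
        raise ValueError("no post-stretch tension rise to fit (stress only decays)")
    tau_w, y_w = tau[itr:], y[itr:]
    if len(tau_w) < 8:
        raise ValueError("post-trough window too short to fit")
    t0_hat = _initial_t0(tau, y)
    r3_0 = t0_coefficient(0.62) / t0_hat
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(n_starts, 1)):
        r0 = (r3_0, 0.62 * r3_0)
        if s > 0:
            j = rng.lognormal(0.0, 0.4, size=2)
            r0 = (r3_0 * j[0], 0.62 * r3_0 * j[1])
        sol = _varpro_fit(tau_w, y_w, r0, _design_reduced)
        if sol is None:
            continue
        ssr, rates, amps = sol
        if best is None or ssr < best[0]:
            best = (ssr, (amps[0], rates[0], rates[1], amps[1]))
    if best is None:
        raise RuntimeError("reduced-kernel fit failed to converge from all starts")
    ssr, (A, r3, r4, base) = best
    if r4 > r3:  # the two-exponential model is symmetric under swap + sign
        r3, r4, A = r4, r3, -A
    kernel = DSAKernel(r3=float(r3), r4=float(r4))
    record = StepResponseFit(
        K2=0.0, K3=0.0, K4=float(A), r2=float("nan"), r3=float(r3),
        r4=float(r4), c=float(base), rmse=math.sqrt(ssr / len(y_w)),
        n_points=len(y_w),
    )
    return kernel, record


# ---------------------------------------------------------------------------
# Non-ideal strain-rate (finite pulse) correction


def iir_scale_factor(
    kernel_curve,
    pulse_width: float,
    pulse_height: float,
    dt: float = 1e-5,
    support: float | None = None,
    reg: float = 1e-9,
) -> float:
    """Ratio of the ideal impulse-response peak to the finite-pulse peak.

    The experimental strain-rate stimulus is a rectangular pulse (width x
    height = strain step), not an impulse, so the measured force peak
    underestimates the impulse response.  Given the fitted force response
    to the pulse (``kernel_curve``: callable t -> force, or a DSAKernel
    whose pulse response is generated internally), the underlying impulse
    response is recovered by frequency-domain deconvolution of the
    unit-area pulse, and the scalar is peak(impulse response to the same
    strain area) / peak(pulse response).  Multiplying the empirical DSA
    magnitude by this scalar gives the impulse-corrected value; the scalar
    tends to 1 as the pulse narrows.
    """
    if pulse_width <= 0 or pulse_height <= 0:
        raise ValueError("pulse width and height must be positive")
    if isinstance(kernel_curve, DSAKernel):
        if support is None:
            support = kernel_curve.t0 + 12.0 / kernel_curve.r4
        n = int(round(support / dt))
        t = np.arange(n) * dt
        npulse = max(int(round(pulse_width / dt)), 1)
        pulse = np.zeros(n)
        pulse[:npulse] = pulse_height
        g = evaluate_kernel(kernel_curve, t)
        response = np.convolve(g, pulse)[:n] * dt
    else:
        if support is None:
            raise ValueError("support must be given for a generic response curve")
        n = int(round(support / dt))
        t = np.arange(n) * dt
        npulse = max(int(round(pulse_width / dt)), 1)
        pulse = np.zeros(n)
        pulse[:npulse] = pulse_height
        response = np.asarray(kernel_curve(t), dtype=float)
    if npulse >= n:
        raise ValueError("pulse wider than the response support")
    area = pulse_height * pulse_width
    # frequency-domain deconvolution with Tikhonov regularization at the
    # sinc zeros of the rectangular pulse spectrum
    nfft = 2 * n
    R = np.fft.rfft(response, nfft)
    P = np.fft.rfft(pulse, nfft) * dt
    P2 = np.abs(P) ** 2
    H = R * np.conj(P) / (P2 + reg * np.max(P2))
    impulse = np.fft.irfft(H, nfft)[:n]
    peak_impulse = float(np.max(impulse)) * area
    peak_pulse = float(np.max(response))
    if peak_pulse <= 0:
        raise ValueError("pulse response has no positive peak")
    return peak_impulse / peak_pulse


# ---------------------------------------------------------------------------
# Work loops


def work_loop_power(
    kernel: DSAKernel,
    Fa: float,
    strain_amplitude: float,
    frequency_grid,
    n_cycles: int = 10,
    samples_per_cycle: int = 200,
) -> tuple[np.ndarray, float]:
    """Per-cycle mean power of the DSA force against sinusoidal strain.

    For imposed strain eps(t) = eps_a sin(2 pi f t) in the linear-response
    regime, the DSA force is Fa (-g * eps_dot) and the mean specific power
    is <F eps_dot> averaged over a steady cycle.  Returns the power array
    over ``frequency_grid`` and the peak-power frequency.  Power is
    positive only above the kernel's crossover frequency sqrt(r3 r4)/2pi
    and vanishes as f -> 0.
    """
    freqs = np.asarray(frequency_grid, dtype=float)
    powers = np.empty_like(freqs)
    for i, f in enumerate(freqs):
        if f <= 0:
            powers[i] = 0.0
            continue
        dt = 1.0 / (f * samples_per_cycle)
        # simulate enough cycles to pass the kernel transient
        warm = int(math.ceil((kernel.t0 + 8.0 / kernel.r4) * f)) + 1
        total = warm + n_cycles
        t = np.arange(total * samples_per_cycle) * dt
        eps_dot = (
            2.0 * math.pi * f * strain_amplitude * np.cos(2.0 * math.pi * f * t)
        )
        g = evaluate_kernel(kernel, np.arange(len(t)) * dt)
        force = -Fa * np.convolve(g, eps_dot)[: len(t)] * dt
        steady = slice(warm * samples_per_cycle, None)
        powers[i] = float(np.mean(force[steady] * eps_dot[steady]))
    ipk = int(np.argmax(powers))
    return powers, float(freqs[ipk])
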