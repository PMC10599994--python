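"""Parameter-plane mapping of combined synchronous/asynchronous actuation.

The K_r x t0/Tn plane organizes the two actuation modes: a synchronous-
entrained tongue near K_r = 1, a self-excited asynchronous region at low
K_r above a critical DSA timescale, and a narrow high-power "bridge"
connecting them where the emergent asynchronous frequency matches the
synchronous drive.  Before sweeping, the forcing gains are tuned so both
endpoints produce the same target wingstroke: Fs for the fully synchronous
system (K_r = 1), and the asynchronous scaling mu for the fully
self-excited system (K_r = 0, at the reference DSA timescale).  The same
tuned gains are then frozen across the whole grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from springwing.actuation import ForcingConfig
from springwing.engine import (
    QUIESCENCE_FLOOR,
    DivergenceError,
    EmergentMetrics,
    SimConfig,
    compute_metrics,
    emergent_frequency,
    simulate,
    steady_amplitude,
)
from springwing.kernel import MANDUCA_KAPPA, DSAKernel, rates_from_t0
from springwing.mechanics import MechanicalPlant

logger = logging.getLogger(__name__)

#: Labels of the dynamic regimes in the parameter plane.
SYNCHRONOUS = "synchronous-entrained"
ASYNCHRONOUS = "asynchronous-dominant"
QUIESCENT = "quiescent"
INTERFERENCE = "interference"


@dataclass(frozen=True)
class SweepConfig:
    """Grid and tuning settings for the K_r x t0/Tn sweep."""

    Kr_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 21)
    )
    t0_over_Tn_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.01, 1.0, 21)
    )
    phi0_target: float = math.radians(117.0)  # peak-to-peak, rad
    fs: float = 25.0
    kappa: float = MANDUCA_KAPPA
    tune_tolerance: float = 0.01
    interference_threshold: float = 0.05  # amp. variation / mean pk-pk
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        for g in (self.Kr_grid, self.t0_over_Tn_grid):
            if np.any(np.diff(g) <= 0):
                raise ValueError("grids must be strictly ascending")
        if self.tune_tolerance <= 0:
            raise ValueError("tune_tolerance must be positive")


@dataclass
class SweepResult:
    """Metric matrices over the (t0/Tn, Kr) grid, shape (n_t0, n_Kr)."""

    Kr_grid: np.ndarray
    t0_over_Tn_grid: np.ndarray
    power: np.ndarray
    f_over_fs: np.ndarray
    amplitude_variation: np.ndarray
    steady_amplitude: np.ndarray
    labels: np.ndarray          # dtype=object regime strings
    mu: float
    Fs: float
    failures: list

    def to_frame(self):
        """Long-format table (Kr, t0_over_Tn, power, f_over_fs, amp_var, label)."""
        import pandas as pd

        rows = []
        for i, x in enumerate(self.t0_over_Tn_grid):
            for j, kr in enumerate(self.Kr_grid):
                rows.append(
                    {
                        "Kr": kr,
                        "t0_over_Tn": x,
                        "power_W": self.power[i, j],
                        "f_over_fs": self.f_over_fs[i, j],
                        "amp_var_rad": self.amplitude_variation[i, j],
                        "steady_amp_rad": self.steady_amplitude[i, j],
                        "label": self.labels[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _forcing(
    plant: MechanicalPlant,
    Kr: float,
    Fs: float,
    fs: float,
    mu: float,
    Fa: float,
    kernel: DSAKernel,
) -> ForcingConfig:
    return ForcingConfig(
        Kr=Kr, Fs=Fs, fs=fs, mu=mu, Fa=Fa, kernel=kernel, L=plant.L, T=plant.T
    )


def _kernel_at(x: float, plant: MechanicalPlant, kappa: float) -> DSAKernel:
    """Kernel whose time-to-peak is x * Tn of the plant (kappa fixed)."""
    r3, r4 = rates_from_t0(x * plant.Tn, kappa)
    return DSAKernel(r3, r4)


def _steady_amp(plant, forcing, sim) -> float:
    try:
        return steady_amplitude(simulate(plant, forcing, sim))
    except DivergenceError:
        return math.inf


def tune_mu(
    plant: MechanicalPlant,
    kernel: DSAKernel,
    Fa: float,
    target: float = math.radians(117.0),
    tolerance: float = 0.01,
    fs: float = 25.0,
    sim: SimConfig | None = None,
    bracket: tuple[float, float] = (1e-3, 1e5),
) -> float:
    """Asynchronous gain mu driving the K_r = 0 system to the target amplitude.

    Coarse logarithmic scan to bracket the target, then bisection until the
    steady peak-to-peak amplitude is within ``tolerance`` (relative).  The
    steady amplitude is verified to be monotone increasing over the scan;
    raises if no oscillation reaches the target anywhere in the bracket.
    """
    sim = sim or SimConfig()

    def amp(mu: float) -> float:
        return _steady_amp(
            plant, _forcing(plant, 0.0, 0.0, fs, mu, Fa, kernel), sim
        )

    mus = np.geomspace(bracket[0], bracket[1], 17)
    amps = np.array([amp(m) for m in mus])
    above = np.nonzero(amps >= target)[0]
    if above.size == 0:
        raise RuntimeError(
            "tuning failure: no oscillation reached the target amplitude; "
            f"scan log: {list(zip(mus.tolist(), amps.tolist()))}"
        )
    hi_i = int(above[0])
    if hi_i == 0:
        raise RuntimeError("tuning failure: bracket lower bound already above target")
    osc = amps[amps > QUIESCENCE_FLOOR]
    if np.any(np.diff(osc) < 0):
        logger.warning("steady amplitude not monotone in mu over the scan bracket")
    lo, hi = float(mus[hi_i - 1]), float(mus[hi_i])
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        a = amp(mid)
        if a < target:
            lo = mid
        else:
            hi = mid
        if abs(a - target) <= tolerance * target:
            return mid
    return hi


def tune_Fs(
    plant: MechanicalPlant,
    fs: float,
    target: float = math.radians(117.0),
    tolerance: float = 0.01,
    kernel: DSAKernel | None = None,
    sim: SimConfig | None = None,
    bracket: tuple[float, float] = (1e-4, 1e3),
) -> float:
    """Synchronous amplitude Fs achieving the target steady amplitude at K_r = 1.

    The kernel is irrelevant at K_r = 1 (no feedback); a reference kernel is
    only needed to build the forcing object.
    """
    sim = sim or SimConfig()
    kernel = kernel or _kernel_at(0.5, plant, MANDUCA_KAPPA)

    def amp(Fs: float) -> float:
        return _steady_amp(
            plant, _forcing(plant, 1.0, Fs, fs, 0.0, 1.0, kernel), sim
        )

    lo, hi = bracket
    if amp(hi) < target:
        raise RuntimeError("tuning failure: bracket upper bound below target")
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        a = amp(mid)
        if a < target:
            lo = mid
        else:
            hi = mid
        if abs(a - target) <= tolerance * target:
            return mid
    return hi


def classify_regime(
    metrics: EmergentMetrics,
    fs: float,
    bin_width: float,
    interference_threshold: float = 0.05,
) -> str:
    """Assign a regime label from the emergent metrics of one cell.

    Synchronous-entrained: oscillating with |f - fs| within one spectral
    bin; interference: oscillating with amplitude variation above the
    threshold fraction of the mean peak-to-peak angle; asynchronous-
    dominant: oscillating elsewhere; quiescent otherwise.
    """
    if metrics.quiescent or metrics.steady_amplitude < QUIESCENCE_FLOOR:
        return QUIESCENT
    entrained = abs(metrics.f_emergent - fs) <= bin_width + 1e-12
    noisy = (
        math.isfinite(metrics.amplitude_variation)
        and metrics.amplitude_variation
        > interference_threshold * metrics.steady_amplitude
    )
    if entrained and not noisy:
        return SYNCHRONOUS
    if noisy:
        return INTERFERENCE
    return ASYNCHRONOUS


def grid_sweep(
    plant: MechanicalPlant,
    config: SweepConfig,
    mu: float,
    Fs: float,
    Fa: float,
) -> SweepResult:
    """Run the full K_r x t0/Tn grid with frozen tuned gains.

    Per-cell divergence is recorded in ``failures`` (cell indices), not
    fatal.  Deterministic given the configuration.
    """
    nx, nk = len(config.t0_over_Tn_grid), len(config.Kr_grid)
    power = np.full((nx, nk), np.nan)
    f_over = np.full((nx, nk), np.nan)
    avar = np.full((nx, nk), np.nan)
    samp = np.full((nx, nk), np.nan)
    labels = np.full((nx, nk), QUIESCENT, dtype=object)
    failures: list = []
    window = 2.5 if config.sim.duration >= 5.0 else config.sim.duration / 2.0
    bin_width = 1.0 / window
    for i, x in enumerate(config.t0_over_Tn_grid):
        kernel = _kernel_at(x, plant, config.kappa)
        for j, kr in enumerate(config.Kr_grid):
            forcing = _forcing(plant, kr, Fs, config.fs, mu, Fa, kernel)
            try:
                res = simulate(plant, forcing, config.sim)
            except DivergenceError as exc:
                failures.append((i, j, str(exc)))
                labels[i, j] = "diverged"
                continue
            m = compute_metrics(res, window=window, require_steady=False)
            power[i, j] = m.power if not m.quiescent else 0.0
            f_over[i, j] = m.f_over_fs
            avar[i, j] = m.amplitude_variation
            samp[i, j] = m.steady_amplitude
            labels[i, j] = classify_regime(
                m, config.fs, bin_width, config.interference_threshold
            )
    return SweepResult(
        Kr_grid=np.asarray(config.Kr_grid, dtype=float),
        t0_over_Tn_grid=np.asarray(config.t0_over_Tn_grid, dtype=float),
        power=power,
        f_over_fs=f_over,
        amplitude_variation=avar,
        steady_amplitude=samp,
        labels=labels,
        mu=mu,
        Fs=Fs,
        failures=failures,
    )


def bifurcation_scan(
    plant: MechanicalPlant,
    mu: float,
    Fa: float,
    kappa: float = MANDUCA_KAPPA,
    scan_range: tuple[float, float] = (0.01, 1.0),
    threshold: float = QUIESCENCE_FLOOR,
    sim: SimConfig | None = None,
    n_bisect: int = 20,
) -> float:
    """Critical t0/Tn for oscillation onset on the fully asynchronous axis.

    Bisection on the steady peak-to-peak amplitude crossing ``threshold``
    (default 1 degree) from the standard 0.1 rad initial condition.  Below
    the critical value the DSA feedback brakes the oscillation; above, a
    finite limit cycle emerges.
    """
    sim = sim or SimConfig()

    def amp(x: float) -> float:
        forcing = _forcing(
            plant, 0.0, 0.0, 25.0, mu, Fa, _kernel_at(x, plant, kappa)
        )
        return _steady_amp(plant, forcing, sim)

    lo, hi = scan_range
    if amp(lo) >= threshold:
        raise ValueError("scan range does not include a quiescent regime")
    if amp(hi) < threshold:
        raise ValueError("scan range does not include an oscillating regime")
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if amp(mid) < threshold:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bridge_origin(
    plant: MechanicalPlant,
    mu: float,
    Fa: float,
    fs: float = 25.0,
    kappa: float = MANDUCA_KAPPA,
    scan_range: tuple[float, float] = (0.05, 1.0),
    sim: SimConfig | None = None,
    n_scan: int = 24,
    n_bisect: int = 16,
) -> float:
    """t0/Tn at which the fully asynchronous emergent frequency equals fs.

    This is the origin of the high-power bridge on the K_r = 0 axis.  A
    coarse scan over the oscillating branch locates a sign change of
    f_emergent - fs (f_emergent is monotone decreasing in t0/Tn there),
    followed by bisection with spectrally refined frequency estimates.
    """
    sim = sim or SimConfig()

    def freq(x: float) -> float:
        forcing = _forcing(plant, 0.0, 0.0, fs, mu, Fa, _kernel_at(x, plant, kappa))
        res = simulate(plant, forcing, sim)
        window = 2.5 if sim.duration >= 5.0 else sim.duration / 2.0
        return emergent_frequency(res, window=window, refine=True)

    xs = np.linspace(scan_range[0], scan_range[1], n_scan)
    fvals = np.array([freq(x) for x in xs])
    osc = fvals > 0
    diffs = fvals - fs
    crossing = None
    for i in range(len(xs) - 1):
        if osc[i] and osc[i + 1] and diffs[i] > 0 >= diffs[i + 1]:
            crossing = i
            break
    if crossing is None:
        raise RuntimeError(
            f"f_emergent never crosses fs={fs} Hz in scan range {scan_range}"
        )
    lo, hi = float(xs[crossing]), float(xs[crossing + 1])
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if freq(mid) - fs > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def entrainment_scan(
    plant: MechanicalPlant,
    mu: float,
    Fa: float,
    kernel: DSAKernel,
    fs_grid,
    forcing_fractions=(0.1, 0.2, 0.3),
    Fs_ref: float = 2.72,
    Kr: float = 0.5,
    sim: SimConfig | None = None,
):
    """Software analogue of the entrainment experiment: emergent frequency
    versus synchronous drive frequency at several forcing fractions.

    Returns a dict mapping each fraction to an array of emergent
    frequencies over ``fs_grid``; the flat f = fs segments delimit the
    Arnold tongue at that forcing strength.
    """
    sim = sim or SimConfig()
    out = {}
    for frac in forcing_fractions:
        fvals = []
        for fs in fs_grid:
            forcing = _forcing(plant, Kr, frac * Fs_ref, fs, mu, Fa, kernel)
            res = simulate(plant, forcing, sim)
            window = 2.5 if sim.duration >= 5.0 else sim.duration / 2.0
            fvals.append(emergent_frequency(res, window=window, refine=True))
        out[frac] = np.asarray(fvals)
    return out
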