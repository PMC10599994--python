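"""Gain tuning, regime classification, bifurcation and bridge location."""

import math

import numpy as np
import pytest

from springwing.engine import EmergentMetrics, SimConfig, compute_metrics, simulate
from springwing.kernel import rates_from_t0, DSAKernel
from springwing.actuation import ForcingConfig
from springwing.sweep import (
    ASYNCHRONOUS,
    INTERFERENCE,
    QUIESCENT,
    SYNCHRONOUS,
    SweepConfig,
    bifurcation_scan,
    bridge_origin,
    classify_regime,
    grid_sweep,
    tune_Fs,
    tune_mu,
)


class TestTuning:
    def test_tuned_mu_hits_target_amplitude(self, plant, reference_kernel,
                                            forcing_defaults, tuned_gains):
        """Round trip: simulating at the tuned mu gives 117 deg within 1%."""
        fc = ForcingConfig(Kr=0.0, Fs=0.0, fs=25.0, mu=tuned_gains["mu"],
                           Fa=forcing_defaults["Fa"], kernel=reference_kernel,
                           L=plant.L, T=plant.T)
        from springwing.engine import steady_amplitude

        amp = steady_amplitude(simulate(plant, fc))
        assert amp == pytest.approx(math.radians(117.0), rel=0.01)

    def test_tuned_fs_recovers_shipped_value(self, plant, tuned_gains):
        """tune_Fs at 25 Hz returns the documented 2.72 N synchronous drive."""
        assert tuned_gains["Fs"] == pytest.approx(2.72, rel=0.02)

    def test_amplitude_monotone_in_mu(self, plant, reference_kernel,
                                      forcing_defaults):
        from springwing.engine import steady_amplitude

        amps = []
        for mu in (10.0, 30.0, 90.0):
            fc = ForcingConfig(Kr=0.0, Fs=0.0, fs=25.0, mu=mu,
                               Fa=forcing_defaults["Fa"],
                               kernel=reference_kernel, L=plant.L, T=plant.T)
            amps.append(steady_amplitude(simulate(plant, fc)))
        assert amps[0] < amps[1] < amps[2]

    def test_doubling_target_increases_mu(self, plant, reference_kernel,
                                          forcing_defaults, tuned_gains):
        mu_big = tune_mu(plant, reference_kernel, forcing_defaults["Fa"],
                         target=math.radians(150.0))
        assert mu_big > tuned_gains["mu"]

    def test_no_drive_is_quiescent(self, plant, forcing_defaults, tuned_gains):
        """Fs = 0 with the DSA feedback in its braking regime decays to rest."""
        r3, r4 = rates_from_t0(0.03 * plant.Tn, 0.62)
        fc = ForcingConfig(Kr=0.5, Fs=0.0, fs=25.0, mu=tuned_gains["mu"],
                           Fa=forcing_defaults["Fa"], kernel=DSAKernel(r3, r4),
                           L=plant.L, T=plant.T)
        m = compute_metrics(simulate(plant, fc))
        assert m.quiescent

    def test_tune_fs_linear_regime_closed_form(self, plant, reference_kernel):
        """With weak damping and a small target, Fs matches the linear
        driven-oscillator closed form within 5%."""
        from dataclasses import replace

        p = replace(plant, Gamma=0.0, c_lin=plant.I * 2.0)
        target = math.radians(2.0)  # peak-to-peak
        fs = 40.0
        Fs = tune_Fs(p, fs, target=target, tolerance=0.005)
        w = 2 * math.pi * fs
        Fs_analytic = (target / 2.0) * p.T * math.hypot(
            p.k_rot - p.I * w**2, p.c_lin * w
        )
        assert Fs == pytest.approx(Fs_analytic, rel=0.05)

    def test_no_oscillation_tuning_failure(self, plant, reference_kernel):
        from springwing.kernel import rates_from_t0

        # below the bifurcation no mu in a tiny bracket oscillates to target
        r3, r4 = rates_from_t0(0.02 * plant.Tn, 0.62)
        with pytest.raises(RuntimeError, match="tuning failure"):
            tune_mu(plant, DSAKernel(r3, r4), 0.3435,
                    bracket=(1e-4, 1e-3))


class TestClassification:
    def _metrics(self, f, amp, var=0.0, quiescent=False):
        return EmergentMetrics(f_emergent=f, f_over_fs=f / 25.0, power=1.0,
                               amplitude_variation=var, steady_amplitude=amp,
                               quiescent=quiescent)

    def test_entrained(self):
        m = self._metrics(25.0, 2.0)
        assert classify_regime(m, 25.0, 0.4) == SYNCHRONOUS

    def test_asynchronous_dominant(self):
        m = self._metrics(18.0, 2.0)
        assert classify_regime(m, 25.0, 0.4) == ASYNCHRONOUS

    def test_interference(self):
        m = self._metrics(18.0, 2.0, var=0.3)
        assert classify_regime(m, 25.0, 0.4) == INTERFERENCE

    def test_quiescent(self):
        m = self._metrics(0.0, 0.0, quiescent=True)
        assert classify_regime(m, 25.0, 0.4) == QUIESCENT


class TestBifurcation:
    def test_critical_t0_over_tn(self, plant, forcing_defaults, tuned_gains):
        """Sharp onset on the Kr=0 axis: braking below, limit cycle above."""
        x_crit = bifurcation_scan(plant, tuned_gains["mu"],
                                  forcing_defaults["Fa"], n_bisect=12)
        assert 0.01 < x_crit < 0.5
        # below: decays from the standard IC; above: finite limit cycle
        from springwing.engine import steady_amplitude

        for x, oscillates in ((x_crit * 0.8, False), (x_crit * 1.2, True)):
            r3, r4 = rates_from_t0(x * plant.Tn, 0.62)
            fc = ForcingConfig(Kr=0.0, Fs=0.0, fs=25.0, mu=tuned_gains["mu"],
                               Fa=forcing_defaults["Fa"],
                               kernel=DSAKernel(r3, r4), L=plant.L, T=plant.T)
            amp = steady_amplitude(simulate(plant, fc))
            assert (amp > math.radians(1.0)) == oscillates

    def test_limit_cycle_independent_of_initial_angle(
        self, plant, forcing_defaults, tuned_gains
    ):
        from springwing.engine import steady_amplitude

        r3, r4 = rates_from_t0(0.54 * plant.Tn, 0.62)
        fc = ForcingConfig(Kr=0.0, Fs=0.0, fs=25.0, mu=tuned_gains["mu"],
                           Fa=forcing_defaults["Fa"], kernel=DSAKernel(r3, r4),
                           L=plant.L, T=plant.T)
        a1 = steady_amplitude(simulate(plant, fc, SimConfig(phi0=0.05)))
        a2 = steady_amplitude(simulate(plant, fc, SimConfig(phi0=0.2)))
        assert a2 == pytest.approx(a1, rel=0.01)

    def test_threshold_drops_with_less_drag(self, plant, forcing_defaults,
                                            tuned_gains):
        from dataclasses import replace

        x1 = bifurcation_scan(plant, tuned_gains["mu"], forcing_defaults["Fa"],
                              n_bisect=8)
        x2 = bifurcation_scan(replace(plant, Gamma=plant.Gamma / 4),
                              tuned_gains["mu"], forcing_defaults["Fa"],
                              n_bisect=8)
        assert x2 <= x1


class TestBridge:
    def test_bridge_origin_frequency_match(self, plant, forcing_defaults,
                                           tuned_gains):
        """At the returned point the emergent frequency equals fs within a
        spectral bin, and f_emergent decreases monotonically in t0/Tn."""
        from springwing.engine import emergent_frequency

        x_star = bridge_origin(plant, tuned_gains["mu"], forcing_defaults["Fa"],
                               fs=25.0, n_scan=12, n_bisect=10)
        r3, r4 = rates_from_t0(x_star * plant.Tn, 0.62)
        fc = ForcingConfig(Kr=0.0, Fs=0.0, fs=25.0, mu=tuned_gains["mu"],
                           Fa=forcing_defaults["Fa"], kernel=DSAKernel(r3, r4),
                           L=plant.L, T=plant.T)
        f = emergent_frequency(simulate(plant, fc))
        assert abs(f - 25.0) <= 0.4
        # monotone decrease over the oscillating branch
        freqs = []
        for x in (0.3, 0.5, 0.8):
            r3, r4 = rates_from_t0(x * plant.Tn, 0.62)
            fc = ForcingConfig(Kr=0.0, Fs=0.0, fs=25.0, mu=tuned_gains["mu"],
                               Fa=forcing_defaults["Fa"],
                               kernel=DSAKernel(r3, r4), L=plant.L, T=plant.T)
            freqs.append(emergent_frequency(simulate(plant, fc)))
        assert freqs[0] > freqs[1] > freqs[2]

    def test_no_crossing_raises(self, plant, forcing_defaults, tuned_gains):
        with pytest.raises(RuntimeError, match="never crosses"):
            bridge_origin(plant, tuned_gains["mu"], forcing_defaults["Fa"],
                          fs=1000.0, scan_range=(0.5, 1.0), n_scan=4)


class TestGridSweep:
    @pytest.fixture(scope="class")
    def small_sweep(self, plant, forcing_defaults, tuned_gains):
        cfg = SweepConfig(
            Kr_grid=np.linspace(0.0, 1.0, 5),
            t0_over_Tn_grid=np.linspace(0.01, 1.0, 5),
        )
        return grid_sweep(plant, cfg, tuned_gains["mu"], tuned_gains["Fs"],
                          forcing_defaults["Fa"]), cfg

    def test_kr_one_row_entrained_everywhere(self, small_sweep):
        """No feedback at Kr = 1: f/fs = 1 independent of t0/Tn."""
        result, _ = small_sweep
        np.testing.assert_allclose(result.f_over_fs[:, -1], 1.0, atol=0.4 / 25)
        assert all(lbl == SYNCHRONOUS for lbl in result.labels[:, -1])

    def test_kr_zero_column_bifurcates(self, small_sweep):
        result, _ = small_sweep
        labels = result.labels[:, 0]
        assert labels[0] == QUIESCENT       # t0/Tn = 0.01 below onset
        assert all(lbl != QUIESCENT for lbl in labels[1:])

    def test_matrix_shapes_and_determinism(self, small_sweep, plant,
                                           forcing_defaults, tuned_gains):
        result, cfg = small_sweep
        assert result.power.shape == (5, 5)
        again = grid_sweep(plant, cfg, tuned_gains["mu"], tuned_gains["Fs"],
                           forcing_defaults["Fa"])
        np.testing.assert_array_equal(result.power, again.power)

    def test_subsampling_consistency(self, small_sweep, plant,
                                     forcing_defaults, tuned_gains):
        """A 3x3 grid equals the matching cells of the 5x5 grid."""
        result, cfg = small_sweep
        sub = SweepConfig(Kr_grid=cfg.Kr_grid[::2],
                          t0_over_Tn_grid=cfg.t0_over_Tn_grid[::2])
        small = grid_sweep(plant, sub, tuned_gains["mu"], tuned_gains["Fs"],
                           forcing_defaults["Fa"])
        np.testing.assert_array_equal(small.power, result.power[::2, ::2])

    def test_long_format_export(self, small_sweep):
        result, _ = small_sweep
        df = result.to_frame()
        assert set(df.columns) >= {"Kr", "t0_over_Tn", "power_W", "f_over_fs",
                                   "amp_var_rad", "label"}
        assert len(df) == 25
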