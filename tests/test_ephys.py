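"""Field-potential quantification: slopes, I/O curves, LTP, coupling."""

import numpy as np
import pytest

from cagephys.ephys import (
    Sweep,
    excitability_ltp_regression,
    gaussian_auc_distribution,
    initial_slope,
    io_curve,
    ltp_series,
    sweeps_from_table,
)
from cagephys.simulate import SweepGroupParams, SweepSimConfig, simulate_sweeps


def _ramp_sweep(slope=1.0, amp=None, dt=0.1, total_ms=40.0, stim_ms=5.0, offset=0.0):
    """Flat trace with a linear negative ramp of the given slope (mV/ms)."""
    t = np.arange(0.0, total_ms + dt / 2, dt)
    v = np.full_like(t, offset)
    onset = stim_ms + 2.0
    amp = amp if amp is not None else slope * 1.0  # 1-ms ramp by default
    ramp_ms = amp / slope
    m = (t >= onset) & (t <= onset + ramp_ms)
    v[m] -= slope * (t[m] - onset)
    v[t > onset + ramp_ms] -= amp
    return Sweep(t_ms=t, v_mV=v, stim_time_ms=stim_ms)


class TestInitialSlope:
    def test_linear_ramp_exact(self):
        s = initial_slope(_ramp_sweep(slope=1.0))
        assert s == pytest.approx(1.0, abs=1e-6)

    def test_flat_trace_flagged_missing(self):
        t = np.arange(0, 40.0, 0.1)
        sw = Sweep(t_ms=t, v_mV=np.zeros_like(t), stim_time_ms=5.0)
        assert initial_slope(sw) is None

    def test_dc_offset_invariance(self):
        s0 = initial_slope(_ramp_sweep(slope=0.8))
        s5 = initial_slope(_ramp_sweep(slope=0.8, offset=5.0))
        assert s5 == pytest.approx(s0, abs=1e-9)

    def test_voltage_scaling_linearity(self):
        sw = _ramp_sweep(slope=0.5)
        scaled = Sweep(t_ms=sw.t_ms, v_mV=3.0 * sw.v_mV, stim_time_ms=sw.stim_time_ms)
        assert initial_slope(scaled) == pytest.approx(
            3.0 * initial_slope(sw), rel=1e-6
        )

    def test_snr20_recovery_within_5pct(self):
        """Programmed slope recovered within 5% from simulated sweeps at
        SNR ~ 20, averaging over 100 replicate sweeps."""
        rng = np.random.default_rng(7)
        cfg = SweepSimConfig(
            groups={
                "g": SweepGroupParams(noise_sd_mV=0.027, slice_gain_sd=0.0)
            },
            n_slices_per_group=1,
            baseline_min=50.0,
            post_min=49.0,
            seed=7,
        )
        tab, truth = simulate_sweeps(cfg)
        by = sweeps_from_table(tab[tab.phase == "ltp"])
        sweeps = by["g_s00"]
        base = [initial_slope(s) for s in sweeps if s.timestamp_min < 0][:100]
        truth_slope = truth["slices"]["g_s00"]["baseline_slope"]
        assert abs(np.mean(base) / truth_slope - 1.0) < 0.05


class TestIOCurve:
    @staticmethod
    def _sweeps(slopes, intensities):
        out = []
        for s, i in zip(slopes, intensities):
            sw = _ramp_sweep(slope=s if s > 0 else 1.0)
            if s <= 0:
                sw.v_mV = np.zeros_like(sw.v_mV)
            sw.stim_intensity = i
            out.append(sw)
        return out

    def test_triangle_auc(self):
        sweeps = self._sweeps([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        io = io_curve(sweeps)
        np.testing.assert_allclose(io.slopes, [0, 1, 2, 3, 4], atol=1e-6)
        assert io.auc == pytest.approx(8.0, abs=1e-5)

    def test_all_zero_slopes(self):
        sweeps = self._sweeps([0] * 5, [1, 2, 3, 4, 5])
        assert io_curve(sweeps).auc == 0.0

    def test_nonmonotone_intensities_rejected(self):
        sweeps = self._sweeps([1, 1, 1, 1, 1], [1, 3, 2, 4, 5])
        with pytest.raises(ValueError):
            io_curve(sweeps)

    def test_doubled_gain_increases_auc(self):
        cfgs = []
        for gain_mult in (1.0, 2.0):
            p = SweepGroupParams(
                io_max_slope=1.2 * gain_mult, noise_sd_mV=0.0, slice_gain_sd=0.0
            )
            cfg = SweepSimConfig(groups={"g": p}, n_slices_per_group=1, seed=0)
            tab, _ = simulate_sweeps(cfg)
            by = sweeps_from_table(tab[tab.phase == "io"])
            cfgs.append(io_curve(by["g_s00"]).auc)
        assert cfgs[1] > cfgs[0]


class TestGaussianAUC:
    def test_ml_closed_form(self):
        mu, sd, dist = gaussian_auc_distribution([1.0, 2.0, 3.0])
        assert mu == pytest.approx(2.0)
        assert sd == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_degenerate_flagged(self):
        with pytest.raises(ValueError):
            gaussian_auc_distribution([2.0, 2.0, 2.0])

    def test_group_shift_recovered(self, rng):
        a = rng.normal(10.0, 2.0, 40)
        b = rng.normal(13.0, 2.0, 40)
        mu_a, sd_a, _ = gaussian_auc_distribution(a)
        mu_b, _, _ = gaussian_auc_distribution(b)
        se = sd_a * np.sqrt(2.0 / 40)
        assert abs((mu_b - mu_a) - 3.0) < 3 * se


class TestLTPSeries:
    @staticmethod
    def _timeline(factors, times):
        sweeps = []
        for f, tm in zip(factors, times):
            sw = _ramp_sweep(slope=0.4 * f)
            sw.timestamp_min = tm
            sweeps.append(sw)
        return sweeps

    def test_null_ltp_constant_100(self):
        times = np.arange(-20.0, 61.0, 1.0)
        sweeps = self._timeline(np.ones_like(times), times)
        lt = ltp_series(sweeps, tbs_time_min=0.0)
        np.testing.assert_allclose(lt.pct_baseline, 100.0, atol=1e-6)
        assert lt.auc == pytest.approx(100.0 * 60.0, rel=1e-9)

    def test_150pct_plateau_auc(self):
        times = np.arange(-20.0, 61.0, 1.0)
        factors = np.where(times < 0, 1.0, 1.5)
        lt = ltp_series(self._timeline(factors, times), tbs_time_min=0.0)
        assert lt.auc == pytest.approx(9000.0, rel=1e-9)

    def test_baseline_mean_is_100_by_construction(self, rng):
        times = np.arange(-20.0, 31.0, 1.0)
        factors = 1.0 + 0.05 * rng.standard_normal(times.size)
        lt = ltp_series(self._timeline(np.abs(factors), times), tbs_time_min=0.0)
        base = lt.pct_baseline[(lt.t_min < 0) & (lt.t_min >= -20)]
        assert base.mean() == pytest.approx(100.0, abs=0.1)

    def test_empty_baseline_rejected(self):
        times = np.arange(0.0, 30.0, 1.0)
        with pytest.raises(ValueError):
            ltp_series(self._timeline(np.ones_like(times), times), tbs_time_min=0.0)

    def test_programmed_plateau_recovered(self):
        cfg = SweepSimConfig(
            groups={
                "g": SweepGroupParams(
                    ltp_plateau_pct=150.0, noise_sd_mV=0.02, slice_gain_sd=0.0
                )
            },
            n_slices_per_group=2,
            seed=9,
        )
        tab, truth = simulate_sweeps(cfg)
        by = sweeps_from_table(tab[tab.phase == "ltp"])
        for sid, sweeps in by.items():
            lt = ltp_series(sweeps, tbs_time_min=0.0)
            plateau = lt.pct_baseline[lt.t_min >= 0].mean()
            want = truth["slices"][sid]["ltp_plateau_pct"]
            assert abs(plateau / want - 1.0) < 0.05


class TestExcitabilityRegression:
    def test_collinear_pairs_unit_correlation(self):
        io = np.array([1.0, 4.0, 9.0, 16.0])
        ltp = 5000.0 - 300.0 * np.sqrt(io)  # exactly linear in sqrt(io)
        reg = excitability_ltp_regression(io, ltp)
        assert reg["r"] == pytest.approx(-1.0)
        assert reg["slope"] == pytest.approx(-300.0)
        assert reg["slope_ci_high"] - reg["slope_ci_low"] == pytest.approx(
            0.0, abs=1e-6
        )

    def test_independent_pairs_ci_covers_zero(self, rng):
        covered = 0
        reps = 200
        for _ in range(reps):
            io = rng.uniform(1, 20, 10)
            ltp = rng.normal(6000, 500, 10)
            reg = excitability_ltp_regression(io, ltp, ci=0.90)
            covered += reg["slope_ci_low"] <= 0.0 <= reg["slope_ci_high"]
        # 90% CI should cover the true slope 0 about 90% of the time
        assert abs(covered / reps - 0.90) < 3 * np.sqrt(0.9 * 0.1 / reps)

    def test_builtin_negative_coupling_recovered(self):
        """Simulated slices with inverse excitability-LTP coupling give a
        negative regression slope in >= 95% of replicates."""
        neg = 0
        reps = 40
        for seed in range(reps):
            cfg = SweepSimConfig(
                groups={
                    "g": SweepGroupParams(
                        coupling=-40.0, slice_gain_sd=0.3, noise_sd_mV=0.02
                    )
                },
                n_slices_per_group=6,
                post_min=30.0,
                seed=seed,
            )
            tab, _ = simulate_sweeps(cfg)
            io_by = sweeps_from_table(tab[tab.phase == "io"])
            ltp_by = sweeps_from_table(tab[tab.phase == "ltp"])
            ioa = [io_curve(io_by[s]).auc for s in sorted(io_by)]
            lta = [ltp_series(ltp_by[s], 0.0).auc for s in sorted(ltp_by)]
            reg = excitability_ltp_regression(np.array(ioa), np.array(lta))
            neg += reg["slope"] < 0
        assert neg >= int(0.95 * reps)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            excitability_ltp_regression([1.0, 2.0], [1.0, 2.0])
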