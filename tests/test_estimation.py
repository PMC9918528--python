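"""Gamma-CDF TTP estimation, Logan analysis, delay metrics, outlier rule."""
import numpy as np
import pytest
from scipy.special import gammainc

import suvrdyn as sd
from suvrdyn.timecourse import TimeGrid


def _synthetic_cdf(grid, amp, shape, onset=30.0, noise=None, rng=None):
    t = np.maximum(grid.times - onset, 0.0)
    y = amp * gammainc(shape, t)
    if noise:
        y = y + noise * rng.standard_normal(y.shape)
    return sd.TimeCourse(grid, y, "delta_suvr")


class TestGammaCDFFit:
    def test_self_recovery_noiseless(self, grid):
        tc = _synthetic_cdf(grid, 0.1, 16.0)
        fit = sd.fit_gamma_cdf(tc, 30.0)
        assert fit.converged
        assert fit.amplitude == pytest.approx(0.1, abs=1e-4)
        assert fit.shape == pytest.approx(16.0, abs=1e-3)
        assert fit.ttp == pytest.approx(15.0, abs=1e-3)

    def test_ttp_equals_shape_minus_one(self, grid):
        fit = sd.fit_gamma_cdf(_synthetic_cdf(grid, 1.0, 11.0), 30.0)
        assert fit.ttp == fit.shape - 1.0

    def test_vertical_scale_invariance_of_ttp(self, grid):
        f1 = sd.fit_gamma_cdf(_synthetic_cdf(grid, 0.5, 12.0), 30.0)
        f2 = sd.fit_gamma_cdf(_synthetic_cdf(grid, 2.0, 12.0), 30.0)
        assert f1.ttp == pytest.approx(f2.ttp, abs=1e-6)

    def test_all_zero_input_flagged(self, grid):
        tc = sd.TimeCourse(grid, np.zeros(len(grid)), "delta_suvr")
        fit = sd.fit_gamma_cdf(tc, 30.0)
        assert not fit.converged

    def test_too_few_samples_is_error(self):
        g = TimeGrid(np.arange(0.5, 36.0, 1.0))
        tc = sd.TimeCourse(g, np.ones(len(g)))
        with pytest.raises(ValueError, match="post-onset"):
            sd.fit_gamma_cdf(tc, 30.0)

    def test_fit_matches_grid_search_on_simulated_curve(self, grid):
        """On the canonical noiseless delta-SUVr, the LM fit agrees with a
        brute-force grid search over (A, s) within 1 min of TTP."""
        import suvrdyn.batch as B
        delta, _, _, _ = B.simulate_pair_batch(
            grid.times, B.nominal_scan_arrays(1), B.nominal_scan_arrays(1),
            B.nominal_occupancy_arrays(1))
        tc = sd.TimeCourse(grid, delta[0], "delta_suvr")
        fit = sd.fit_gamma_cdf(tc, 30.0)
        tp = grid.times[grid.times >= 30.0] - 30.0
        y = delta[0][grid.times >= 30.0]
        shapes = np.arange(2.0, 60.0, 0.25)
        amps = np.arange(0.05, 10.0, 0.05)
        rss = np.array([[np.sum((a * gammainc(s, tp) - y) ** 2)
                         for s in shapes] for a in amps])
        ia, ish = np.unravel_index(np.argmin(rss), rss.shape)
        assert fit.ttp == pytest.approx(shapes[ish] - 1.0, abs=1.0)

    def test_noise_degrades_ttp_monotonically(self, grid):
        """The spread of fitted TTP grows with the noise level."""
        rng = np.random.default_rng(8)
        sds = []
        for cv in (0.005, 0.02, 0.06):
            ttps = []
            for _ in range(60):
                tc = _synthetic_cdf(grid, 1.0, 16.0, noise=cv, rng=rng)
                fit = sd.fit_gamma_cdf(tc, 30.0)
                if fit.converged:
                    ttps.append(fit.ttp)
            sds.append(np.std(ttps, ddof=1))
        assert sds[0] < sds[1] < sds[2]


class TestLogan:
    def test_target_equals_reference(self, placebo_tacs_1min):
        ref, _ = placebo_tacs_1min
        fit = sd.logan_ref(ref, ref)
        assert fit.bp_nd == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("t_star", [15.0, 20.0, 25.0])
    def test_placebo_bp_matches_kinetic_ratio(self, placebo_tacs_1min, t_star):
        ref, tgt = placebo_tacs_1min
        fit = sd.logan_ref(tgt, ref, t_star=t_star)
        expected = sd.LSSRMParams().bp_nd  # 5.92
        assert fit.bp_nd == pytest.approx(expected, rel=0.02)

    def test_scale_invariance(self, placebo_tacs_1min):
        ref, tgt = placebo_tacs_1min
        a = sd.logan_ref(tgt, ref).dvr
        b = sd.logan_ref(tgt.with_values(3 * tgt.values),
                         ref.with_values(3 * ref.values)).dvr
        assert a == pytest.approx(b, rel=1e-9)

    def test_grid_must_extend_beyond_t_star(self):
        g = TimeGrid(np.arange(0.5, 15.0, 1.0))
        tc = sd.TimeCourse(g, np.ones(len(g)))
        with pytest.raises(ValueError):
            sd.logan_ref(tc, tc, t_star=20.0)


class TestMeasureDelay:
    def test_identical_curves(self, grid):
        y = 1.0 / (1.0 + np.exp(-(grid.times - 45.0) / 5.0))
        tc = sd.TimeCourse(grid, y)
        assert sd.measure_delay(tc, tc) == 0.0

    @pytest.mark.parametrize("method,tol", [("half_max", 0.05), ("xcorr", 0.2)])
    def test_constructed_shift(self, grid, method, tol):
        f = lambda t: 1.0 / (1.0 + np.exp(-(t - 40.0) / 5.0))
        a = sd.TimeCourse(grid, f(grid.times))
        b = sd.TimeCourse(grid, f(grid.times - 5.0))
        assert sd.measure_delay(a, b, method) == pytest.approx(5.0, abs=tol)

    def test_flat_curve_is_error(self, grid):
        tc = sd.TimeCourse(grid, np.zeros(len(grid)))
        with pytest.raises(ValueError, match="half"):
            sd.measure_delay(tc, tc)


class TestTrueRateTTP:
    def test_gamma_cdf_trajectory(self):
        g = TimeGrid(np.arange(0.0, 90.0001, 0.01))
        s = 16.0
        D = gammainc(s, g.times)
        traj = sd.OccupancyDATrajectory(g, np.zeros(len(g)), np.zeros(len(g)),
                                        D, admin_time=0.0)
        assert sd.true_rate_ttp(traj) == pytest.approx(s - 1.0, abs=0.02)

    def test_linear_d_has_no_peak(self):
        g = TimeGrid(np.arange(0.0, 90.0001, 0.5))
        traj = sd.OccupancyDATrajectory(g, np.zeros(len(g)), np.zeros(len(g)),
                                        0.01 * g.times, admin_time=0.0)
        with pytest.raises(ValueError):
            sd.true_rate_ttp(traj)

    def test_canonical_iv_in_window(self, iv_trajectory):
        ttp = sd.true_rate_ttp(iv_trajectory)
        assert 0.0 < ttp < 60.0


class TestOutlierFlagging:
    def test_all_equal_none_flagged(self):
        assert not sd.flag_ttp_outliers([10.0] * 6).any()

    def test_single_outlier_flagged(self):
        flags = sd.flag_ttp_outliers([10, 10, 10, 10, 10, 20])
        assert list(flags) == [False] * 5 + [True]

    def test_tight_sample_none_flagged(self):
        assert not sd.flag_ttp_outliers([10, 12, 11, 9, 10]).any()

    def test_too_few_values_is_error(self):
        with pytest.raises(ValueError):
            sd.flag_ttp_outliers([1.0, 2.0])
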