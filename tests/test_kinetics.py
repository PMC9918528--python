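"""Input functions and ODE systems: closed-form anchors and invariants."""
import numpy as np
import pytest

import suvrdyn as sd
import suvrdyn.batch as B
from suvrdyn.timecourse import TimeGrid


class TestRacloInput:
    def test_zero_at_injection(self):
        assert sd.eval_raclo_input(0.0) == 0.0

    def test_peak_value_and_continuity(self):
        p = sd.RacloInputParams()
        peak = sd.eval_raclo_input(p.t_peak, p)
        assert peak == pytest.approx(p.A1 + p.A2 + p.A3)  # 699.4 Bq/ml
        eps = 1e-9
        assert sd.eval_raclo_input(p.t_peak - eps, p) == pytest.approx(peak, rel=1e-6)

    def test_monotone_decreasing_tail(self):
        t = np.linspace(sd.RacloInputParams().t_peak, 90.0, 2000)
        v = sd.eval_raclo_input(t)
        assert np.all(np.diff(v) < 0)
        assert v[-1] < v[0]

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            sd.eval_raclo_input(-1.0)


class TestMPPlasma:
    def test_iv_amplitude_at_admin(self):
        p = sd.MPPlasmaParams()
        assert sd.eval_mp_plasma(p.admin_time, p) == pytest.approx(0.25)

    def test_iv_half_life(self):
        p = sd.MPPlasmaParams()
        t_half = p.admin_time + np.log(2) / p.lam
        assert sd.eval_mp_plasma(t_half, p) == pytest.approx(p.A / 2)

    def test_zero_before_admin(self):
        p = sd.MPPlasmaParams.oral()
        assert sd.eval_mp_plasma(p.admin_time - 0.5, p) == 0.0

    def test_oral_mode_at_t_peak(self):
        p = sd.MPPlasmaParams.oral()
        t = np.linspace(-30.0, 200.0, 23001)
        v = sd.eval_mp_plasma(t, p)
        t_mode = t[np.argmax(v)]
        assert t_mode == pytest.approx(p.admin_time + p.t_peak_oral, abs=0.05)


class TestReferenceTac:
    def test_zero_input_gives_zero(self, grid):
        tc = sd.simulate_reference_tac(lambda t: 0.0,
                                       sd.ReferenceKineticParams(), grid)
        assert np.allclose(tc.values, 0.0)

    def test_step_input_equilibrium(self):
        grid = TimeGrid(np.linspace(0.0, 60.0, 601))
        p = sd.ReferenceKineticParams()
        tc = sd.simulate_reference_tac(lambda t: 100.0, p, grid)
        assert tc.values[-1] == pytest.approx(p.K1r / p.k2r * 100.0, rel=1e-4)

    def test_unimodal_peak_after_input_peak(self, placebo_tacs, dense_grid):
        ref, _ = placebo_tacs
        i = int(np.argmax(ref.values))
        assert dense_grid.times[i] > sd.RacloInputParams().t_peak
        assert 0 < i < len(dense_grid) - 1

    def test_linearity_in_input(self, grid):
        p = sd.ReferenceKineticParams()
        a = sd.simulate_reference_tac(lambda t: 50.0 * np.exp(-0.1 * t), p, grid)
        b = sd.simulate_reference_tac(lambda t: 100.0 * np.exp(-0.1 * t), p, grid)
        assert np.allclose(2 * a.values, b.values, rtol=1e-6, atol=1e-9)


class TestOccupancyDA:
    def test_no_drug_stays_zero(self, dense_grid):
        p = sd.MPPlasmaParams(dose_scale=0.0)
        traj = sd.simulate_occupancy_da(sd.MPKineticParams(), p, sd.DAParams(),
                                        dense_grid)
        assert np.allclose(traj.f_occ, 0.0) and np.allclose(traj.D, 0.0)

    def test_iv_peak_occupancy_range(self, iv_trajectory):
        # ~70% DAT blockade for the canonical IV dose
        assert 0.55 < iv_trajectory.peak_occupancy() < 0.8

    def test_zero_before_admin(self, iv_trajectory, dense_grid):
        pre = dense_grid.times < 30.0
        assert np.allclose(iv_trajectory.f_occ[pre], 0.0)
        assert np.allclose(iv_trajectory.D[pre], 0.0)

    @pytest.mark.parametrize("c", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_clamped_equilibrium(self, c):
        beta = 0.02
        t_end = 10.0 / (beta * (1.0 - c))
        grid = TimeGrid(np.linspace(0.0, t_end, 2001))
        d = sd.kinetics.simulate_da_clamped(c, beta, grid)
        assert d[-1] == pytest.approx(c / (1.0 - c), rel=1e-3)

    def test_occupancy_bounded_under_parameter_draws(self):
        rng = np.random.default_rng(11)
        n = 1000
        occ = B.nominal_occupancy_arrays(n)
        for k in ("K1_MP", "k2_MP", "k3_MP", "k4_MP", "beta", "dose_scale"):
            occ[k] = occ[k] * (1 + 0.10 * np.clip(rng.standard_normal(n), -4, 4))
        _, R, f, D = B.solve_occupancy_batch(occ)
        assert np.all(f >= 0) and np.all(f < 1)
        assert np.all(D >= -1e-12)


class TestGammaVariateH:
    def test_zero_before_delay(self):
        assert sd.eval_gamma_variate_h(30.0) == 0.0

    def test_unit_peak(self):
        assert sd.eval_gamma_variate_h(45.0) == pytest.approx(1.0)

    def test_value_at_twice_rise(self):
        p = sd.GammaVariateHParams()
        t = p.t_D + 2 * (p.t_p - p.t_D)
        assert sd.eval_gamma_variate_h(t, p) == pytest.approx(2 * np.exp(-1))


class TestMakeH:
    def test_peak_normalization(self, iv_trajectory):
        for model in ("DAT_OCCUPANCY", "DA_INCREASE"):
            h = sd.make_h(model, iv_trajectory)
            assert np.max(h.values) == pytest.approx(1.0)
            assert np.all(h.values[h.times < 30.0] == 0.0)

    def test_da_model_peaks_later_than_occupancy(self, iv_trajectory):
        h_f = sd.make_h("DAT_OCCUPANCY", iv_trajectory)
        h_d = sd.make_h("DA_INCREASE", iv_trajectory)
        half = lambda h: h.times[np.argmax(h.values >= 0.5)]
        assert half(h_d) > half(h_f)

    def test_all_zero_trajectory_rejected(self, dense_grid):
        traj = sd.simulate_occupancy_da(
            sd.MPKineticParams(), sd.MPPlasmaParams(dose_scale=0.0),
            sd.DAParams(), dense_grid)
        with pytest.raises(ValueError, match="normalize"):
            sd.make_h("DA_INCREASE", traj)


class TestTargetTac:
    def test_srtm_reduction(self, dense_grid):
        """With no displacement, R1 = 1 and k2 = k2a the target equals the
        reference exactly."""
        ref = sd.simulate_reference_tac(sd.RacloInputParams(),
                                        sd.ReferenceKineticParams(), dense_grid)
        p = sd.LSSRMParams(R1=1.0, k2=0.065, k2a=0.065, gamma=0.0)
        tgt = sd.simulate_target_tac(ref, p, None, dense_grid)
        assert np.allclose(tgt.values, ref.values,
                           rtol=1e-5, atol=1e-6 * ref.values.max())

    def test_zero_h_equals_zero_gamma(self, dense_grid, iv_trajectory):
        ref = sd.simulate_reference_tac(sd.RacloInputParams(),
                                        sd.ReferenceKineticParams(), dense_grid)
        h0 = sd.TimeCourse(dense_grid, np.zeros(len(dense_grid)), "h")
        a = sd.simulate_target_tac(ref, sd.LSSRMParams(), h0, dense_grid)
        b = sd.simulate_target_tac(ref, sd.LSSRMParams(gamma=0.0), None,
                                   dense_grid)
        assert np.allclose(a.values, b.values, rtol=1e-8, atol=1e-8)

    def test_grid_mismatch_rejected(self, dense_grid, grid, iv_trajectory):
        ref = sd.simulate_reference_tac(sd.RacloInputParams(),
                                        sd.ReferenceKineticParams(), dense_grid)
        h = sd.TimeCourse(grid, np.zeros(len(grid)), "h")
        with pytest.raises(ValueError, match="share a grid"):
            sd.simulate_target_tac(ref, sd.LSSRMParams(), h, dense_grid)

    def test_integral_and_differential_forms_agree(self, iv_trajectory):
        from scipy.integrate import cumulative_simpson
        g = TimeGrid(np.arange(0.0, 90.0001, 0.005))
        ref = sd.simulate_reference_tac(sd.RacloInputParams(),
                                        sd.ReferenceKineticParams(), g)
        occ = sd.simulate_occupancy_da(sd.MPKineticParams(), sd.MPPlasmaParams(),
                                       sd.DAParams(), g)
        h = sd.make_h("DA_INCREASE", occ)
        p = sd.LSSRMParams()
        ct = sd.simulate_target_tac(ref, p, h, g)
        icr = cumulative_simpson(ref.values, x=g.times, initial=0.0)
        ict = cumulative_simpson(ct.values, x=g.times, initial=0.0)
        ihct = cumulative_simpson(ct.values * h.values, x=g.times, initial=0.0)
        rhs = p.R1 * ref.values + p.k2 * icr - p.k2a * ict - p.gamma * ihct
        assert np.max(np.abs(rhs - ct.values)) < 1e-6 * ct.values.max()


class TestBatchEngine:
    """The vectorized fixed-step integrator must agree with the adaptive
    reference solver."""

    def test_occupancy_agreement(self, iv_trajectory, dense_grid):
        _, R, f, D = B.solve_occupancy_batch(B.nominal_occupancy_arrays(1))
        assert np.max(np.abs(f[:, 0] - iv_trajectory.f_occ)) < 1e-4
        assert np.max(np.abs(D[:, 0] - iv_trajectory.D)) < 1e-4 * iv_trajectory.D.max()
        # the bolus step discontinuity leaves a node-local artifact in R only
        assert np.max(np.abs(R[:, 0] - iv_trajectory.R)) < 5e-4 * iv_trajectory.R.max()

    def test_tac_agreement(self, placebo_tacs, dense_grid, iv_trajectory):
        ref, _ = placebo_tacs
        h = sd.make_h("DA_INCREASE", iv_trajectory)
        tgt = sd.simulate_target_tac(ref, sd.LSSRMParams(), h, dense_grid)
        times, Rb, fb, Db = B.solve_occupancy_batch(B.nominal_occupancy_arrays(1))
        hb = Db / Db.max(axis=0)
        t, Cr, Ct = B.solve_scan_batch(B.nominal_scan_arrays(1), hb)
        cr = np.interp(dense_grid.times, t, Cr[:, 0])
        ct = np.interp(dense_grid.times, t, Ct[:, 0])
        assert np.max(np.abs(cr - ref.values)) < 1e-4 * ref.values.max()
        assert np.max(np.abs(ct - tgt.values)) < 1e-4 * tgt.values.max()


class TestOralCalibration:
    def test_oral_peak_occupancy_matches_iv(self, iv_trajectory):
        g = TimeGrid(np.arange(-30.0, 90.0001, 0.05))
        traj = sd.simulate_occupancy_da(sd.MPKineticParams(),
                                        sd.MPPlasmaParams.oral(),
                                        sd.DAParams(), g)
        assert traj.peak_occupancy() == pytest.approx(
            iv_trajectory.peak_occupancy(), abs=0.01)
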