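"""Monte-Carlo validation experiments for the dual-scan delta-SUVr method.

Each experiment simulates paired placebo/challenge scans under a controlled
source of variability, fits the gamma-CDF time-to-peak per replicate, and
summarizes over converged, non-outlier replicates (exclusions are counted,
never silent).  All randomness derives from the spec's master seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import batch
from .estimation import GammaCDFFit, fit_gamma_cdf, flag_ttp_outliers, measure_delay
from .params import (
    DAParams,
    MPKineticParams,
    MPPlasmaParams,
    RacloInputParams,
    ReferenceKineticParams,
    LSSRMParams,
)
from .timecourse import TimeCourse, TimeGrid, default_grid

__all__ = ["JitterSpec", "ExperimentResult", "run_specificity_experiment",
           "run_dose_sensitivity", "run_injection_jitter",
           "run_within_pair_variability", "run_lssrm_variability",
           "run_between_subject_associations", "run_ttp_recovery"]


@dataclass(frozen=True)
class JitterSpec:
    """Monte-Carlo settings.

    ``between_cv``/``within_cv`` are the between-replicate and
    between-scan coefficient-of-variation levels; ``injection_sd`` is the
    injection-time jitter in seconds; ``noise_cv`` the SUVr measurement
    noise.
    """

    between_cv: float = 0.10
    within_cv: float = 0.04
    injection_sd: float = 120.0   # seconds
    noise_cv: float = 0.03
    noise_mode: str = "multiplicative"
    n_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.between_cv, self.within_cv, self.injection_sd,
               self.noise_cv) < 0:
            raise ValueError("jitter settings must be nonnegative")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


@dataclass
class ExperimentResult:
    """Per-replicate table plus summary statistics.

    ``table`` has one row per replicate (drawn parameters, fitted TTP,
    convergence and outlier flags); ``summary`` holds the experiment's
    headline numbers computed over converged, non-outlier replicates.
    """

    name: str
    table: pd.DataFrame
    summary: dict = field(default_factory=dict)

    @property
    def n_converged(self) -> int:
        return int(self.table["converged"].sum())

    @property
    def n_excluded(self) -> int:
        return int(len(self.table) - (self.table["converged"]
                                      & ~self.table["outlier"]).sum())


# --------------------------------------------------------------------------
# internals

def _cv_draw(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Multiplicative CV draw, truncated at +-4 SD to keep rates positive."""
    return 1.0 + cv * np.clip(rng.standard_normal(n), -4.0, 4.0)


_INPUT_KEYS = ("A1", "A2", "A3", "T1", "T2", "T3", "t_peak")
_KINETIC_KEYS = ("K1r", "R1", "k2", "k2a")


def _perturb_scan(scan: dict, rng: np.random.Generator, cv: float,
                  keys: Sequence[str]) -> dict:
    out = dict(scan)
    n = scan["K1r"].shape[0]
    for k in keys:
        out[k] = scan[k] * _cv_draw(rng, n, cv)
    return out


def _fit_batch(delta: np.ndarray, grid: TimeGrid, onset: float) -> pd.DataFrame:
    rows = []
    for row in delta:
        fit = fit_gamma_cdf(TimeCourse(grid, row, "delta_suvr"), onset)
        rows.append((fit.amplitude, fit.ttp, fit.converged))
    return pd.DataFrame(rows, columns=["amplitude", "ttp", "converged"])


def _mark_outliers(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["outlier"] = False
    conv = df["converged"] & np.isfinite(df["ttp"])
    if conv.sum() >= 3:
        df.loc[conv, "outlier"] = flag_ttp_outliers(df.loc[conv, "ttp"].to_numpy())
    return df


def _kept(df: pd.DataFrame) -> pd.Series:
    return df["converged"] & ~df["outlier"] & np.isfinite(df["ttp"])


def _route_setup(route: str):
    if route.upper() == "IV":
        plasma = MPPlasmaParams()
    elif route.upper() == "ORAL":
        plasma = MPPlasmaParams.oral()
    else:
        raise ValueError("route must be 'IV' or 'ORAL'")
    return plasma, plasma.admin_time


# --------------------------------------------------------------------------
# experiments

def run_specificity_experiment(grid: TimeGrid | None = None) -> dict:
    """Model specificity: delta-SUVr under h from DAT occupancy vs h from
    dopamine increase, identical kinetics, noiseless.

    Reports the delay between the two delta-SUVr curves (both delay metrics)
    and the shape correlation of each normalized h model with its own
    normalized delta-SUVr curve.
    """
    grid = grid or default_grid()
    n1 = 1
    occ = batch.nominal_occupancy_arrays(n1)
    times_occ, R, f, D = batch.solve_occupancy_batch(occ)
    offset = int(round(-times_occ[0] / (batch.DT_TAC / 2)))
    scan = batch.nominal_scan_arrays(n1)

    deltas = {}
    for name, prof in (("f_occ", f), ("D", D)):
        h = (prof / prof.max(axis=0))[offset:]
        _, Cr0, Ct0 = batch.solve_scan_batch(scan, None)
        times, Cr, Ct = batch.solve_scan_batch(scan, h)
        idx = np.searchsorted(times, grid.times)
        deltas[name] = (Ct0[idx] / Cr0[idx] - Ct[idx] / Cr[idx])[:, 0]

    tc_f = TimeCourse(grid, deltas["f_occ"], "delta_suvr")
    tc_d = TimeCourse(grid, deltas["D"], "delta_suvr")
    out = {
        "delay_half_max": measure_delay(tc_f, tc_d, "half_max"),
        "delay_xcorr": measure_delay(tc_f, tc_d, "xcorr"),
    }
    # shape correlation of each h model with its own delta-SUVr, post onset
    post = grid.times >= 30.0
    for name, prof in (("f_occ", f), ("D", D)):
        hvals = np.interp(grid.times, times_occ, prof[:, 0] / prof[:, 0].max())
        d = deltas[name] / np.max(deltas[name])
        out[f"shape_corr_{name}"] = float(np.corrcoef(hvals[post], d[post])[0, 1])
    return out


def run_dose_sensitivity(dose_scales: Sequence[float] = (0.5, 1.0, 2.0),
                         grid: TimeGrid | None = None) -> pd.DataFrame:
    """Peak delta-SUVr as a function of MP dose (noiseless).

    The displacement profile is scaled against the canonical-condition
    dopamine peak, so dose modulates both the timing and the amplitude of
    the simulated dopamine response.
    """
    if len(dose_scales) < 2:
        raise ValueError("need at least two dose levels")
    grid = grid or default_grid()
    rows = []
    for ds in dose_scales:
        occ = batch.nominal_occupancy_arrays(1)
        occ["dose_scale"] = np.array([ds])
        delta, true_ttp, _, _ = batch.simulate_pair_batch(
            grid.times, batch.nominal_scan_arrays(1),
            batch.nominal_scan_arrays(1), occ)
        rows.append((ds, float(np.nanmax(delta)), float(true_ttp[0])))
    df = pd.DataFrame(rows, columns=["dose_scale", "peak_delta_suvr",
                                     "true_rate_ttp"])
    df = df.sort_values("dose_scale").reset_index(drop=True)
    amp = df["peak_delta_suvr"].to_numpy()
    ds = df["dose_scale"].to_numpy()
    df.attrs["monotone_increasing"] = bool(np.all(np.diff(amp) > 0))
    pos = amp[:-1] > 0
    df.attrs["sublinear"] = bool(np.all(
        (amp[1:][pos] / amp[:-1][pos]) < (ds[1:][pos] / ds[:-1][pos])))
    return df


def run_injection_jitter(spec: JitterSpec, target: str = "RACLO_BOLUS",
                         route: str = "IV") -> ExperimentResult:
    """Robustness of fitted TTP to injection-time errors.

    Per replicate, the targeted bolus time (tracer in the challenge scan, or
    the MP bolus) is shifted by N(0, injection_sd); SUVr noise is applied;
    the spread (SD) of fitted TTP across replicates is the headline number.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sims
    grid = default_grid()
    plasma, onset = _route_setup(route)
    shift = (spec.injection_sd / 60.0) * rng.standard_normal(n)
    scan_pl = batch.nominal_scan_arrays(n)
    scan_mp = batch.nominal_scan_arrays(n)
    occ = batch.nominal_occupancy_arrays(n, plasma=plasma)
    if target.upper() == "RACLO_BOLUS":
        scan_mp["t_inj"] = shift
    elif target.upper() == "MP_BOLUS":
        occ["admin_time"] = occ["admin_time"] + shift
    else:
        raise ValueError("target must be 'RACLO_BOLUS' or 'MP_BOLUS'")
    delta, true_ttp, _, _ = batch.simulate_pair_batch(
        grid.times, scan_pl, scan_mp, occ,
        noise_cv=spec.noise_cv, noise_mode=spec.noise_mode, rng=rng)
    df = _fit_batch(delta, grid, onset)
    df["shift_min"] = shift
    df["true_rate_ttp"] = true_ttp
    df = _mark_outliers(df)
    kept = _kept(df)
    summary = {
        "delta_ttp_sd": float(df.loc[kept, "ttp"].std(ddof=1)),
        "ttp_mean": float(df.loc[kept, "ttp"].mean()),
        "n_kept": int(kept.sum()),
        "n_nonconverged": int((~df["converged"]).sum()),
        "n_outlier": int(df["outlier"].sum()),
    }
    return ExperimentResult(f"injection_jitter_{target.lower()}", df, summary)


def run_within_pair_variability(spec: JitterSpec, route: str = "IV") -> ExperimentResult:
    """Within-pair physiologic variability: independent ``within_cv`` draws
    of the tracer input parameters and the reference/target kinetic
    parameters for each scan of the pair."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sims
    grid = default_grid()
    plasma, onset = _route_setup(route)
    keys = _INPUT_KEYS + _KINETIC_KEYS
    scan_pl = _perturb_scan(batch.nominal_scan_arrays(n), rng, spec.within_cv, keys)
    scan_mp = _perturb_scan(batch.nominal_scan_arrays(n), rng, spec.within_cv, keys)
    occ = batch.nominal_occupancy_arrays(n, plasma=plasma)
    delta, true_ttp, _, _ = batch.simulate_pair_batch(
        grid.times, scan_pl, scan_mp, occ,
        noise_cv=spec.noise_cv, noise_mode=spec.noise_mode, rng=rng)
    df = _fit_batch(delta, grid, onset)
    df["true_rate_ttp"] = true_ttp
    df = _mark_outliers(df)
    kept = _kept(df)
    summary = {
        "delta_ttp_sd": float(df.loc[kept, "ttp"].std(ddof=1)),
        "ttp_mean": float(df.loc[kept, "ttp"].mean()),
        "n_kept": int(kept.sum()),
        "n_nonconverged": int((~df["converged"]).sum()),
        "n_outlier": int(df["outlier"].sum()),
    }
    return ExperimentResult("within_pair_variability", df, summary)


def run_lssrm_variability(spec: JitterSpec, route: str = "IV") -> ExperimentResult:
    """Between-replicate ``between_cv`` variation of the target-model
    parameters only (R1, k2, k2a, gamma; shared by both scans of a pair).

    The headline number is the mean absolute deviation of fitted TTP from
    the unperturbed fit.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sims
    grid = default_grid()
    plasma, onset = _route_setup(route)
    base = batch.nominal_scan_arrays(n)
    for k in ("R1", "k2", "k2a", "gamma"):
        base[k] = base[k] * _cv_draw(rng, n, spec.between_cv)
    occ = batch.nominal_occupancy_arrays(n, plasma=plasma)
    delta, _, _, _ = batch.simulate_pair_batch(
        grid.times, base, base, occ,
        noise_cv=spec.noise_cv, noise_mode=spec.noise_mode, rng=rng)
    # unperturbed, noiseless baseline fit
    d0, _, _, _ = batch.simulate_pair_batch(
        grid.times, batch.nominal_scan_arrays(1), batch.nominal_scan_arrays(1),
        batch.nominal_occupancy_arrays(1, plasma=plasma))
    ttp0 = fit_gamma_cdf(TimeCourse(grid, d0[0], "delta_suvr"), onset).ttp
    df = _fit_batch(delta, grid, onset)
    df = _mark_outliers(df)
    kept = _kept(df)
    dev = (df.loc[kept, "ttp"] - ttp0).abs()
    summary = {
        "mean_abs_delta_ttp": float(dev.mean()),
        "ttp_unperturbed": float(ttp0),
        "n_kept": int(kept.sum()),
        "n_nonconverged": int((~df["converged"]).sum()),
        "n_outlier": int(df["outlier"].sum()),
    }
    return ExperimentResult("lssrm_variability", df, summary)


def run_between_subject_associations(spec: JitterSpec, route: str = "IV") -> ExperimentResult:
    """Between-subject variability: ``between_cv`` draws of the MP dose, the
    plasma timing parameter (lambda for IV, absorption peak for oral), the
    tracer input parameters and the kinetic parameters; univariate R-squared
    of fitted TTP on each drawn parameter."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sims
    grid = default_grid()
    plasma, onset = _route_setup(route)
    cv = spec.between_cv
    scan = _perturb_scan(batch.nominal_scan_arrays(n), rng, cv,
                         _INPUT_KEYS + _KINETIC_KEYS + ("gamma",))
    occ = batch.nominal_occupancy_arrays(n, plasma=plasma)
    dose = _cv_draw(rng, n, cv)
    occ["dose_scale"] = occ["dose_scale"] * dose
    draws = {"dose": dose}
    if plasma.route == "IV":
        occ["lam"] = occ["lam"] * _cv_draw(rng, n, cv)
        draws["lam"] = occ["lam"]
    else:
        occ["t_peak_oral"] = occ["t_peak_oral"] * _cv_draw(rng, n, cv)
        draws["t_peak_oral"] = occ["t_peak_oral"]
    for k in _INPUT_KEYS + _KINETIC_KEYS + ("gamma",):
        draws[k] = scan[k]
    delta, true_ttp, _, _ = batch.simulate_pair_batch(
        grid.times, scan, scan, occ,
        noise_cv=spec.noise_cv, noise_mode=spec.noise_mode, rng=rng)
    df = _fit_batch(delta, grid, onset)
    for k, v in draws.items():
        df[f"draw_{k}"] = v
    df["true_rate_ttp"] = true_ttp
    df = _mark_outliers(df)
    kept = _kept(df).to_numpy()
    ttp = df.loc[kept, "ttp"].to_numpy()
    r2 = {}
    for k, v in draws.items():
        x = np.asarray(v)[kept]
        r = np.corrcoef(x, ttp)[0, 1] if np.std(x) > 0 else 0.0
        r2[k] = float(r * r)
    summary = {
        "r_squared": r2,
        "ttp_sd": float(np.std(ttp, ddof=1)),
        "n_kept": int(kept.sum()),
        "n_nonconverged": int((~df["converged"]).sum()),
        "n_outlier": int(df["outlier"].sum()),
    }
    return ExperimentResult(f"associations_{route.lower()}", df, summary)


def run_ttp_recovery(spec: JitterSpec, route: str = "IV") -> ExperimentResult:
    """Recovery of the true dopamine-rate TTP by the gamma-CDF fit.

    The plasma decay rate is held fixed; all other parameters (tracer input,
    kinetic, displacement, occupancy-system and dose) vary with
    ``within_cv``; SUVr noise applies.  Reports the Pearson correlation
    between fitted and true TTP and the mean/SD of their absolute
    difference."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sims
    grid = default_grid()
    plasma, onset = _route_setup(route)
    cv = spec.within_cv
    scan = _perturb_scan(batch.nominal_scan_arrays(n), rng, cv,
                         _INPUT_KEYS + _KINETIC_KEYS + ("gamma",))
    occ = batch.nominal_occupancy_arrays(n, plasma=plasma)
    for k in ("K1_MP", "k2_MP", "k3_MP", "k4_MP", "beta"):
        occ[k] = occ[k] * _cv_draw(rng, n, cv)
    if plasma.route == "ORAL":
        occ["t_peak_oral"] = occ["t_peak_oral"] * _cv_draw(rng, n, cv)
    occ["dose_scale"] = occ["dose_scale"] * _cv_draw(rng, n, cv)
    delta, true_ttp, _, _ = batch.simulate_pair_batch(
        grid.times, scan, scan, occ,
        noise_cv=spec.noise_cv, noise_mode=spec.noise_mode, rng=rng)
    df = _fit_batch(delta, grid, onset)
    df["true_rate_ttp"] = true_ttp
    df = _mark_outliers(df)
    kept = _kept(df)
    fitted = df.loc[kept, "ttp"].to_numpy()
    true = df.loc[kept, "true_rate_ttp"].to_numpy()
    if fitted.size < 3 or np.std(fitted) == 0 or np.std(true) == 0:
        pearson_r = float("nan")
    else:
        pearson_r = float(np.corrcoef(fitted, true)[0, 1])
    adiff = np.abs(fitted - true)
    summary = {
        "pearson_r": pearson_r,
        "mean_abs_delta_ttp": float(np.mean(adiff)),
        "sd_abs_delta_ttp": float(np.std(adiff, ddof=1)),
        "n_kept": int(kept.sum()),
        "n_nonconverged": int((~df["converged"]).sum()),
        "n_outlier": int(df["outlier"].sum()),
    }
    return ExperimentResult(f"ttp_recovery_{route.lower()}", df, summary)
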