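"""Model-free estimation: gamma-CDF time-to-peak, Logan reference analysis,
curve-delay metrics, and outlier flagging.

The central estimator fits the two-parameter gamma cumulative distribution

    F(t') = A / Gamma(s) * int_0^{t'} e^{-x} x^{s-1} dx,   t' = t - onset,

to a delta-SUVr curve (unit scale, minutes).  The time-to-peak of the
corresponding density f = dF/dt is the mode of a unit-scale gamma,
TTP = s - 1, reported relative to the challenge onset.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammainc
from scipy.stats import pearsonr  # noqa: F401  (re-exported convenience)

from .kinetics import OccupancyDATrajectory
from .timecourse import TimeCourse

__all__ = ["GammaCDFFit", "LoganFit", "fit_gamma_cdf", "logan_ref",
           "measure_delay", "true_rate_ttp", "flag_ttp_outliers"]

#: parameter bounds: s <= 1 is a non-identifiable plateau (TTP <= 0), very
#: large s means the rise never happened inside the scan window
_S_BOUNDS = (1.0 + 1e-9, 200.0)
_A_BOUNDS = (1e-9, 10.0)
_MIN_POINTS = 10


@dataclass(frozen=True)
class GammaCDFFit:
    """Result of the gamma-CDF fit.  ``ttp`` equals ``shape - 1`` exactly."""

    amplitude: float
    shape: float
    ttp: float
    converged: bool
    rss: float
    n_points: int


def _half_rise_time(t: np.ndarray, y: np.ndarray) -> float | None:
    ymax = np.max(y)
    if ymax <= 0:
        return None
    half = ymax / 2.0
    idx = np.nonzero(y >= half)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    if i == 0:
        return float(t[0])
    return float(t[i - 1] + (half - y[i - 1]) / (y[i] - y[i - 1]) * (t[i] - t[i - 1]))


def fit_gamma_cdf(delta: TimeCourse, mp_onset: float) -> GammaCDFFit:
    """Least-squares gamma-CDF fit to a delta-SUVr curve.

    Only samples at ``t >= mp_onset`` enter the fit (t' = t - mp_onset).
    Non-convergence and degenerate data are reported through the
    ``converged`` flag, never raised, so Monte-Carlo batches always
    complete.  Fewer than 10 usable post-onset samples is an error.
    """
    mask = delta.times >= mp_onset
    tp = delta.times[mask] - mp_onset
    y = delta.values[mask]
    ok = np.isfinite(y)
    tp, y = tp[ok], y[ok]
    if tp.size < _MIN_POINTS:
        raise ValueError(f"need >= {_MIN_POINTS} post-onset samples, got {tp.size}")
    if np.max(y) <= 0:
        return GammaCDFFit(np.nan, np.nan, np.nan, False,
                           float(np.sum(y ** 2)), tp.size)

    half_rise = _half_rise_time(tp, y)
    s0 = np.clip(max(2.0, (half_rise if half_rise is not None else 5.0) + 1.0),
                 1.01, 199.0)
    tail = y[-min(10, y.size):]
    a0 = np.clip(float(np.mean(tail)), 1e-3, _A_BOUNDS[1])

    def resid(p):
        return p[0] * gammainc(p[1], tp) - y

    try:
        sol = least_squares(resid, [a0, s0],
                            bounds=([_A_BOUNDS[0], _S_BOUNDS[0]],
                                    [_A_BOUNDS[1], _S_BOUNDS[1]]),
                            max_nfev=400)
    except Exception:
        return GammaCDFFit(np.nan, np.nan, np.nan, False, np.nan, tp.size)
    amp, shape = float(sol.x[0]), float(sol.x[1])
    rss = float(np.sum(sol.fun ** 2))
    converged = bool(sol.success) and shape > 1.0 + 1e-6 and amp > 1e-6 \
        and shape < _S_BOUNDS[1] - 1e-6
    return GammaCDFFit(amp, shape, shape - 1.0, converged, rss, tp.size)


@dataclass(frozen=True)
class LoganFit:
    """Reference-tissue Logan graphical analysis result."""

    dvr: float
    bp_nd: float
    t_star: float
    r_squared: float
    n_used: int
    n_dropped: int


def logan_ref(target: TimeCourse, ref: TimeCourse, t_star: float = 20.0,
              k2_ref: float | None = 0.45) -> LoganFit:
    """Logan plot with a reference-region input.

    Ordinary least squares of Y = int_0^t C_T / C_T against
    X = (int_0^t C_r + C_r / k2') / C_T over samples with t >= t_star; the
    slope is the distribution volume ratio, BPnd = DVR - 1.  ``k2_ref=None``
    omits the reference-efflux correction term.  Non-finite transform points
    (early frames with no activity) are dropped and counted.
    """
    if target.times.shape != ref.times.shape or \
            not np.allclose(target.times, ref.times):
        raise ValueError("target and reference must share a grid")
    t = target.times
    if t[-1] <= t_star:
        raise ValueError("grid must extend beyond t_star")
    ict = _running_integral(t, target.values)
    icr = _running_integral(t, ref.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = icr / target.values
        if k2_ref is not None:
            x = x + ref.values / (k2_ref * target.values)
        yv = ict / target.values
    sel = (t >= t_star) & np.isfinite(x) & np.isfinite(yv)
    dropped = int(np.sum((t >= t_star) & ~(np.isfinite(x) & np.isfinite(yv))))
    if np.sum(sel) < 3:
        raise ValueError("too few usable samples beyond t_star")
    slope, intercept = np.polyfit(x[sel], yv[sel], 1)
    pred = slope * x[sel] + intercept
    ss_res = float(np.sum((yv[sel] - pred) ** 2))
    ss_tot = float(np.sum((yv[sel] - np.mean(yv[sel])) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LoganFit(float(slope), float(slope) - 1.0, t_star, r2,
                    int(np.sum(sel)), dropped)


def _running_integral(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Trapezoidal running integral from the start of the scan.

    The first sample is treated as the end of a linear rise from zero
    activity at t = 0 when the grid starts after the injection.
    """
    out = np.empty_like(y)
    lead = 0.5 * y[0] * t[0] if t[0] > 0 else 0.0
    out[0] = lead
    out[1:] = lead + np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(t))
    return out


def measure_delay(a: TimeCourse, b: TimeCourse, method: str = "half_max") -> float:
    """Delay of curve ``b`` relative to ``a`` (positive when b lags).

    ``half_max`` (default): difference of the times at which each curve
    first crosses half of its own maximum.  ``xcorr``: the shift maximizing
    the correlation between the two curves on a 0.1-min interpolated grid.
    Both expect monotone-rise (noiseless or smoothed) curves.
    """
    if method == "half_max":
        ta = _half_rise_time(a.times, a.values)
        tb = _half_rise_time(b.times, b.values)
        if ta is None or tb is None:
            raise ValueError("a curve never reaches half of its maximum")
        return tb - ta
    if method == "xcorr":
        t0, t1 = a.times[0], a.times[-1]
        tt = np.arange(t0, t1, 0.1)
        av, bv = a.interp(tt), b.interp(tt)
        max_shift = int(0.5 * tt.size)
        best, best_r = 0.0, -np.inf
        for k in range(-max_shift, max_shift):
            if k >= 0:
                x, yv = av[: tt.size - k] if k else av, bv[k:] if k else bv
            else:
                x, yv = av[-k:], bv[: tt.size + k]
            if x.size < 10 or np.std(x) == 0 or np.std(yv) == 0:
                continue
            r = float(np.corrcoef(x, yv)[0, 1])
            if r > best_r:
                best_r, best = r, k * 0.1
        return best
    raise ValueError("method must be 'half_max' or 'xcorr'")


def true_rate_ttp(traj: OccupancyDATrajectory, mp_onset: float | None = None) -> float:
    """Time of the maximum dopamine-increase rate, relative to ``mp_onset``.

    Central differences of D(t) on the trajectory grid; an interior maximum
    is required (a linear or constant D has no time-to-peak).
    """
    onset = traj.admin_time if mp_onset is None else mp_onset
    if np.allclose(traj.D, traj.D[0]):
        raise ValueError("D(t) is constant; rate has no peak")
    d = np.gradient(traj.D, traj.grid.times)
    if np.ptp(d) <= 1e-12 * max(1.0, np.max(np.abs(d))):
        raise ValueError("dD/dt is constant; rate has no peak")
    i = int(np.argmax(d))
    if i == len(d) - 1:
        # still rising at the end of the grid: no interior maximum
        raise ValueError("dD/dt has no interior maximum on the grid")
    return float(traj.grid.times[i] - onset)


def flag_ttp_outliers(ttps) -> np.ndarray:
    """Boolean flags for TTP values more than 2 sample SDs from the mean.

    The candidate is included in the mean/SD (single pass).  Flagged entries
    are excluded from downstream summaries by the experiment layer.
    """
    x = np.asarray(ttps, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values to flag outliers")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - np.mean(x)) > 2.0 * sd
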