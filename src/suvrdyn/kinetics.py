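"""Plasma input functions and the tissue / occupancy / dopamine ODE systems.

The model chain for one challenge scan:

1. tracer plasma input  C_p(t)  (tri-exponential bolus),
2. reference tissue     dC_r/dt = K1r C_p - k2r C_r,
3. MP occupancy system  dR/dt   = K1 Rp - k2 R - k3 (1-f) R + k4 f,
                        df/dt   = k3 (1-f) R - k4 f,
4. dopamine increase    dD/dt   = beta [ f - (1-f) D ],
5. target tissue (LSSRM) C_T(t) = R1 C_r + k2 int C_r - k2a int C_T
                                  - gamma int h C_T,

with h(t) the normalized displacement profile derived from f(t) or D(t)
(mechanistic models) or from a heuristic gamma-variate.

Single-trajectory solves use an adaptive LSODA integrator (automatic
stiffness switching); the Monte-Carlo experiments use the vectorized
fixed-step integrator in :mod:`suvrdyn.batch`, which is validated against
this module.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.integrate import solve_ivp

from .params import (
    DAParams,
    GammaVariateHParams,
    MPKineticParams,
    MPPlasmaParams,
    RacloInputParams,
    ReferenceKineticParams,
    LSSRMParams,
)
from .timecourse import TimeCourse, TimeGrid

__all__ = [
    "eval_raclo_input",
    "eval_mp_plasma",
    "eval_gamma_variate_h",
    "simulate_reference_tac",
    "simulate_occupancy_da",
    "simulate_da_clamped",
    "make_h",
    "simulate_target_tac",
    "calibrate_oral_amplitude",
    "OccupancyDATrajectory",
]

_RTOL = 1e-8
_ATOL = 1e-10
LN2 = float(np.log(2.0))


def eval_raclo_input(t, p: RacloInputParams = RacloInputParams()):
    """Tracer plasma concentration (Bq/ml) at time(s) ``t`` minutes.

    Linear rise to ``A1+A2+A3`` at ``t_peak``; tri-exponential decay
    (half-lives ``T1..T3``) referenced to ``t_peak`` afterwards.  The two
    branches agree at ``t_peak``.  Negative times are a domain error (the
    input is defined from the tracer injection).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("tracer input is defined for t >= 0 only")
    asum = p.A1 + p.A2 + p.A3
    rise = asum / p.t_peak * t
    tt = t - p.t_peak
    decay = (p.A1 * np.exp(-LN2 / p.T1 * tt)
             + p.A2 * np.exp(-LN2 / p.T2 * tt)
             + p.A3 * np.exp(-LN2 / p.T3 * tt))
    out = np.where(t < p.t_peak, rise, decay)
    return out if out.ndim else float(out)


def eval_mp_plasma(t, p: MPPlasmaParams = MPPlasmaParams()):
    """Relative MP plasma concentration Rp(t); zero before ``admin_time``."""
    t = np.asarray(t, dtype=float)
    tt = t - p.admin_time
    amp = p.A * p.dose_scale
    if p.route == "IV":
        out = np.where(tt < 0, 0.0, amp * np.exp(-p.lam * np.maximum(tt, 0.0)))
    else:
        # peak-normalized unit-scale gamma density: shape k+1, mode at k
        k = p.t_peak_oral
        with np.errstate(divide="ignore", invalid="ignore"):
            lg = k * (np.log(np.maximum(tt, 1e-300)) - np.log(k)) - (tt - k)
        out = np.where(tt <= 0, 0.0, amp * np.exp(lg))
    return out if out.ndim else float(out)


def eval_gamma_variate_h(t, p: GammaVariateHParams = GammaVariateHParams()):
    """Heuristic gamma-variate displacement profile; 0 before the delay,
    peak value 1 at ``t_p``."""
    t = np.asarray(t, dtype=float)
    x = (t - p.t_D) / (p.t_p - p.t_D)
    with np.errstate(invalid="ignore"):
        out = np.where(t < p.t_D, 0.0,
                       np.maximum(x, 0.0) ** p.theta
                       * np.exp(p.theta * (1.0 - x)))
    return out if out.ndim else float(out)


InputLike = Union[TimeCourse, RacloInputParams, Callable[[float], float]]


def _as_callable(inp: InputLike) -> Callable:
    if isinstance(inp, TimeCourse):
        return inp.interp
    if isinstance(inp, RacloInputParams):
        return lambda t: eval_raclo_input(np.maximum(t, 0.0), inp)
    return inp


def simulate_reference_tac(inp: InputLike,
                           p: ReferenceKineticParams,
                           grid: TimeGrid,
                           t_inj: float = 0.0) -> TimeCourse:
    """One-tissue reference TAC on ``grid`` for plasma input ``inp``.

    ``t_inj`` shifts the tracer injection (the input is evaluated at
    ``t - t_inj`` and the tissue is empty before the injection).
    """
    cp = _as_callable(inp)

    def rhs(t, y):
        c = cp(t - t_inj) if t >= t_inj else 0.0
        return [p.K1r * c - p.k2r * y[0]]

    t0 = min(float(grid.times[0]), t_inj, 0.0)
    sol = solve_ivp(rhs, (t0, float(grid.times[-1])), [0.0],
                    t_eval=grid.times, method="LSODA",
                    rtol=_RTOL, atol=_ATOL, max_step=0.5)
    if not sol.success:
        raise RuntimeError(f"reference TAC integration failed: {sol.message}")
    return TimeCourse(grid, np.maximum(sol.y[0], 0.0), "reference")


@dataclass(frozen=True)
class OccupancyDATrajectory:
    """Joint solution of the MP occupancy and dopamine systems.

    ``R`` is the relative free MP concentration, ``f_occ`` the fractional
    DAT occupancy (in [0, 1)), ``D`` the scaled relative dopamine increase;
    all zero at the administration time.
    """

    grid: TimeGrid
    R: np.ndarray
    f_occ: np.ndarray
    D: np.ndarray
    admin_time: float

    def peak_occupancy(self) -> float:
        return float(np.max(self.f_occ))


def simulate_occupancy_da(p_mp: MPKineticParams,
                          p_plasma: MPPlasmaParams,
                          p_da: DAParams,
                          grid: TimeGrid) -> OccupancyDATrajectory:
    """Integrate the MP occupancy and dopamine ODEs on ``grid``.

    Integration starts at ``min(grid start, admin_time)`` with
    R = f_occ = D = 0; the system stays at zero until the drug arrives.
    Parameter sets that drive the occupancy to 1 (or beyond) are rejected:
    occupancy cannot exceed the total transporter pool.
    """
    def rhs(t, y):
        R, f, D = y
        rp = eval_mp_plasma(t, p_plasma)
        dR = (p_mp.K1_MP * rp - p_mp.k2_MP * R
              - p_mp.k3_MP * (1.0 - f) * R + p_mp.k4_MP * f)
        df = p_mp.k3_MP * (1.0 - f) * R - p_mp.k4_MP * f
        dD = p_da.beta * (f - (1.0 - f) * D)
        return [dR, df, dD]

    # the system is identically zero before the drug arrives; starting the
    # integration at the administration time avoids stepping across the kink
    t_admin = p_plasma.admin_time
    active = grid.times >= t_admin
    R = np.zeros(len(grid)); f = np.zeros(len(grid)); D = np.zeros(len(grid))
    if np.any(active):
        t_eval = grid.times[active]
        sol = solve_ivp(rhs, (min(t_admin, t_eval[0]), float(t_eval[-1])),
                        [0.0, 0.0, 0.0], t_eval=t_eval, method="LSODA",
                        rtol=_RTOL, atol=_ATOL, max_step=0.5)
        if not sol.success:
            raise RuntimeError(f"occupancy integration failed: {sol.message}")
        R[active], f[active], D[active] = sol.y
    if np.any(f >= 1.0):
        raise ValueError("fractional occupancy reached 1: parameter set "
                         "implies more bound MP than transporters")
    return OccupancyDATrajectory(grid, R, np.clip(f, 0.0, None),
                                 np.maximum(D, 0.0), p_plasma.admin_time)


def simulate_da_clamped(f_const: float, beta: float, grid: TimeGrid) -> np.ndarray:
    """Dopamine response when the occupancy is clamped at ``f_const``.

    Test mode for the equilibrium property: D converges to f/(1-f) with
    rate beta (1-f).
    """
    if not 0.0 <= f_const < 1.0:
        raise ValueError("clamped occupancy must lie in [0, 1)")

    def rhs(t, y):
        return [beta * (f_const - (1.0 - f_const) * y[0])]

    sol = solve_ivp(rhs, (float(grid.times[0]), float(grid.times[-1])), [0.0],
                    t_eval=grid.times, method="LSODA", rtol=_RTOL, atol=_ATOL)
    if not sol.success:
        raise RuntimeError(sol.message)
    return sol.y[0]


def make_h(model: str, source, grid: TimeGrid | None = None,
           norm_peak: float | None = None) -> TimeCourse:
    """Displacement profile h(t) for the LSSRM efflux term.

    Parameters
    ----------
    model :
        ``"DAT_OCCUPANCY"`` (h from f_occ), ``"DA_INCREASE"`` (h from D) or
        ``"GAMMA_VARIATE"`` (heuristic Eq.-style profile).
    source :
        An :class:`OccupancyDATrajectory` for the mechanistic models, or
        :class:`GammaVariateHParams` for the heuristic one.
    norm_peak :
        Normalization constant.  By default the profile's own in-window peak
        is used, so max h = 1 (model-comparison convention).  The Monte-Carlo
        experiments pass the canonical-condition peak instead, so that dose
        and parameter draws modulate the displacement amplitude.

    h is zero before the administration time and the normalization is taken
    over the scan window only.  An all-zero profile cannot be normalized and
    raises ``ValueError``.
    """
    model = model.upper()
    if model == "GAMMA_VARIATE":
        if grid is None:
            raise ValueError("GAMMA_VARIATE requires a grid")
        vals = eval_gamma_variate_h(grid.times, source)
        return TimeCourse(grid, np.asarray(vals), "h")
    if not isinstance(source, OccupancyDATrajectory):
        raise TypeError("mechanistic h models require an OccupancyDATrajectory")
    traj = source
    raw = traj.f_occ if model == "DAT_OCCUPANCY" else traj.D
    if model not in ("DAT_OCCUPANCY", "DA_INCREASE"):
        raise ValueError(f"unknown h model: {model}")
    peak = float(np.max(raw)) if norm_peak is None else float(norm_peak)
    if peak <= np.finfo(float).eps:
        raise ValueError("cannot normalize an all-zero displacement profile")
    vals = raw / peak
    vals = np.where(traj.grid.times < traj.admin_time, 0.0, vals)
    return TimeCourse(traj.grid, vals, "h")


def simulate_target_tac(ref: TimeCourse,
                        p: LSSRMParams,
                        h: TimeCourse | None,
                        grid: TimeGrid) -> TimeCourse:
    """LSSRM striatal TAC on ``grid``.

    Solves the differential form of the LSSRM operational equation; with
    ``z = C_T - R1 C_r`` the reference-derivative term drops out:

        dz/dt = k2 C_r - (k2a + gamma h) (R1 C_r + z),   z(0) = 0.

    ``h=None`` disables the displacement term (placebo scan).  ``ref`` and
    ``h`` must share a grid.
    """
    if h is not None and h.grid.times.shape != ref.grid.times.shape:
        raise ValueError("reference TAC and h must share a grid")
    if h is not None and not np.allclose(h.grid.times, ref.grid.times):
        raise ValueError("reference TAC and h must share a grid")
    cr = ref.interp
    hv = (lambda t: 0.0) if h is None else h.interp

    def rhs(t, y):
        c = cr(t)
        loss = p.k2a + p.gamma * hv(t)
        return [p.k2 * c - loss * (p.R1 * c + y[0])]

    t0 = float(ref.grid.times[0])
    sol = solve_ivp(rhs, (min(t0, 0.0), float(grid.times[-1])), [0.0],
                    t_eval=grid.times, method="LSODA",
                    rtol=_RTOL, atol=_ATOL, max_step=0.5)
    if not sol.success:
        raise RuntimeError(f"target TAC integration failed: {sol.message}")
    ct = p.R1 * ref.interp(grid.times) + sol.y[0]
    return TimeCourse(grid, ct, "target")


def calibrate_oral_amplitude(p_mp: MPKineticParams = MPKineticParams(),
                             p_da: DAParams = DAParams(),
                             target_peak_occ: float | None = None,
                             t_end: float = 90.0,
                             tol: float = 1e-4) -> float:
    """Oral plasma amplitude whose peak DAT occupancy matches the IV condition.

    The oral input shape carries no absolute scale, so the amplitude is set
    by requiring dose equivalence in transporter blockade (as the oral and IV
    doses of the study were chosen to produce).
    """
    dense = TimeGrid(np.arange(-30.0, t_end + 1e-9, 0.1))
    if target_peak_occ is None:
        iv_dense = TimeGrid(np.arange(0.0, t_end + 1e-9, 0.1))
        iv = simulate_occupancy_da(p_mp, MPPlasmaParams(), p_da, iv_dense)
        target_peak_occ = iv.peak_occupancy()
    lo, hi = 1e-3, 50.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        traj = simulate_occupancy_da(
            p_mp, MPPlasmaParams.oral(A=mid), p_da, dense)
        if traj.peak_occupancy() < target_peak_occ:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
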