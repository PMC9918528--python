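"""Kinetic and input-function parameter sets.

Defaults are the canonical simulation conditions for a dual-scan
[11C]raclopride methylphenidate (MP) challenge: a bolus tracer injection at
t = 0, an IV-MP bolus at +30 min (or an oral dose at -30 min), a one-tissue
cerebellum reference region, and an LSSRM striatal target whose efflux is
transiently increased by dopamine-raclopride binding competition.

Units are minutes and 1/min throughout.  Note on the tri-exponential plasma
input: the component half-lives T1..T3 are interpreted on the minute scale
(4.28, 735.5 and 183.5 min); a seconds-scale reading would drive the
reference-region activity to zero mid-scan and make the SUVr ratio diverge,
which is incompatible with a reference-tissue framework.  The rise time
t_peak is 110 s = 1.8333 min.

Every dataclass round-trips through ``to_dict``/``from_dict`` (used by the
JSON config layer); unknown keys are rejected.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

__all__ = [
    "RacloInputParams",
    "ReferenceKineticParams",
    "LSSRMParams",
    "GammaVariateHParams",
    "MPKineticParams",
    "MPPlasmaParams",
    "DAParams",
    "ScanPairParams",
]

#: default IV-MP administration time (minutes after tracer injection)
IV_MP_TIME = 30.0
#: default oral-MP administration time (minutes before tracer injection)
ORAL_MP_TIME = -30.0
#: oral plasma amplitude calibrated so peak DAT occupancy matches the IV
#: condition (see kinetics.calibrate_oral_amplitude)
ORAL_AMPLITUDE = 0.1611


class _Serializable:
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]):
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
        return cls(**d)


def _require_positive(obj, *names: str) -> None:
    for name in names:
        if not getattr(obj, name) > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0")


@dataclass(frozen=True)
class RacloInputParams(_Serializable):
    """Tri-exponential arterial input for the tracer.

    Linear rise to ``A1 + A2 + A3`` at ``t_peak``, then a sum of three
    exponentials with half-lives ``T1..T3`` referenced to ``t_peak``.
    """

    A1: float = 288.6   # Bq/ml
    A2: float = 1.1
    A3: float = 409.7
    T1: float = 4.28    # min (half-life of component 1)
    T2: float = 735.5
    T3: float = 183.5
    t_peak: float = 110.0 / 60.0  # min

    def __post_init__(self) -> None:
        _require_positive(self, "A1", "A2", "A3", "T1", "T2", "T3", "t_peak")


@dataclass(frozen=True)
class ReferenceKineticParams(_Serializable):
    """One-tissue model for the reference region (cerebellum)."""

    K1r: float = 0.092  # mL/min/g
    k2r: float = 0.45   # 1/min

    def __post_init__(self) -> None:
        _require_positive(self, "K1r", "k2r")


@dataclass(frozen=True)
class LSSRMParams(_Serializable):
    """Linear simplified reference region model with time-varying efflux.

    ``gamma`` is the amplitude of the ligand-displacement term gamma*h(t)
    (1/min).  The implied baseline binding potential is ``k2/k2a - 1``.
    """

    R1: float = 1.154
    k2: float = 0.45     # 1/min
    k2a: float = 0.065   # 1/min
    gamma: float = 0.18  # 1/min

    def __post_init__(self) -> None:
        _require_positive(self, "R1", "k2", "k2a")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.k2 / self.k2a - 1 < 0:
            raise ValueError("implied baseline BPnd (k2/k2a - 1) must be >= 0")

    @property
    def bp_nd(self) -> float:
        return self.k2 / self.k2a - 1.0


@dataclass(frozen=True)
class GammaVariateHParams(_Serializable):
    """Heuristic gamma-variate displacement profile h(t)."""

    t_D: float = 31.0   # min, delay
    t_p: float = 45.0   # min, peak
    theta: float = 1.0  # shape

    def __post_init__(self) -> None:
        if not self.t_p > self.t_D:
            raise ValueError("t_p must exceed t_D")
        _require_positive(self, "theta")


@dataclass(frozen=True)
class MPKineticParams(_Serializable):
    """Two-tissue transfer rate constants for methylphenidate."""

    K1_MP: float = 0.6   # 1/min
    k2_MP: float = 0.06
    k3_MP: float = 0.5
    k4_MP: float = 0.2

    def __post_init__(self) -> None:
        _require_positive(self, "K1_MP", "k2_MP", "k3_MP", "k4_MP")


@dataclass(frozen=True)
class MPPlasmaParams(_Serializable):
    """Relative MP plasma concentration Rp(t) = Cp_MP / DAT0.

    IV route: ``A * dose_scale * exp(-lambda (t - admin_time))``.
    Oral route: peak-normalized unit-scale gamma density with mode at
    ``t_peak_oral`` minutes after ``admin_time``, scaled by
    ``A * dose_scale``; the default oral amplitude is calibrated so the
    peak DAT occupancy matches the IV condition.
    """

    route: str = "IV"            # "IV" | "ORAL"
    A: float = 0.25              # relative amplitude
    lam: float = 0.05            # 1/min (IV decay)
    t_peak_oral: float = 90.0    # min (mode of oral absorption curve)
    admin_time: float = IV_MP_TIME  # min relative to tracer injection
    dose_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.route not in ("IV", "ORAL"):
            raise ValueError("route must be 'IV' or 'ORAL'")
        _require_positive(self, "A")
        if self.route == "IV" and not self.lam > 0:
            raise ValueError("lambda must be > 0 for IV")
        if self.route == "ORAL" and not self.t_peak_oral > 0:
            raise ValueError("t_peak_oral must be > 0 for ORAL")
        if self.dose_scale < 0:
            raise ValueError("dose_scale must be >= 0")

    @classmethod
    def oral(cls, **kw) -> "MPPlasmaParams":
        kw.setdefault("route", "ORAL")
        kw.setdefault("A", ORAL_AMPLITUDE)
        kw.setdefault("admin_time", ORAL_MP_TIME)
        return cls(**kw)


@dataclass(frozen=True)
class DAParams(_Serializable):
    """Dopamine clearance rate constant beta (1/min).

    The release rate is eliminated by scaling the dopamine concentration, so
    beta is the single free parameter of the dopamine compartment.
    """

    beta: float = 0.02

    def __post_init__(self) -> None:
        _require_positive(self, "beta")


@dataclass(frozen=True)
class ScanPairParams(_Serializable):
    """All parameters for one placebo/challenge scan pair."""

    raclo_pl: RacloInputParams = RacloInputParams()
    raclo_mp: RacloInputParams = RacloInputParams()
    ref_pl: ReferenceKineticParams = ReferenceKineticParams()
    ref_mp: ReferenceKineticParams = ReferenceKineticParams()
    lssrm_pl: LSSRMParams = LSSRMParams()
    lssrm_mp: LSSRMParams = LSSRMParams()
    mp_kinetics: MPKineticParams = MPKineticParams()
    mp_plasma: MPPlasmaParams = MPPlasmaParams()
    da: DAParams = DAParams()
    t_inj_pl: float = 0.0  # tracer injection time, placebo scan (min)
    t_inj_mp: float = 0.0  # tracer injection time, challenge scan (min)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name).to_dict()
                if hasattr(getattr(self, f.name), "to_dict")
                else getattr(self, f.name)
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScanPairParams":
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(d) - set(types)
        if unknown:
            raise ValueError(f"unknown keys for ScanPairParams: {sorted(unknown)}")
        sub = {"raclo_pl": RacloInputParams, "raclo_mp": RacloInputParams,
               "ref_pl": ReferenceKineticParams, "ref_mp": ReferenceKineticParams,
               "lssrm_pl": LSSRMParams, "lssrm_mp": LSSRMParams,
               "mp_kinetics": MPKineticParams, "mp_plasma": MPPlasmaParams,
               "da": DAParams}
        kw: dict[str, Any] = {}
        for k, v in d.items():
            kw[k] = sub[k].from_dict(v) if k in sub else v
        return cls(**kw)
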