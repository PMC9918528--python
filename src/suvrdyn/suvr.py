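"""SUVr and delta-SUVr time courses, measurement noise, frame resampling."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timecourse import TimeCourse, TimeGrid

__all__ = ["SUVrPair", "compute_suvr", "delta_suvr", "add_noise",
           "resample_to_frames"]

#: samples within this window after an ideal bolus may legitimately have
#: near-zero reference activity and are masked rather than divided
_BOLUS_MASK_MIN = 1.0
#: reference-activity floor (Bq/ml) below which the ratio is unreliable
_REF_FLOOR = 1e-6


def compute_suvr(target: TimeCourse, ref: TimeCourse) -> TimeCourse:
    """Pointwise target/reference ratio.

    Samples inside the first minute where the reference is still (near) zero
    are masked to NaN; a floor violation later in the scan is an error, since
    it means the reference TAC is unusable as a normalizer.
    """
    if target.times.shape != ref.times.shape or \
            not np.allclose(target.times, ref.times):
        raise ValueError("target and reference must share a grid")
    r = ref.values
    low = r <= _REF_FLOOR
    if np.any(low & (ref.times >= _BOLUS_MASK_MIN)):
        raise ValueError("reference activity below floor after the bolus window")
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(low, np.nan, target.values / np.where(low, 1.0, r))
    return TimeCourse(target.grid, vals, "suvr")


@dataclass(frozen=True)
class SUVrPair:
    """Placebo and challenge SUVr curves on a shared grid."""

    placebo: TimeCourse
    challenge: TimeCourse

    def __post_init__(self) -> None:
        if self.placebo.times.shape != self.challenge.times.shape or \
                not np.allclose(self.placebo.times, self.challenge.times):
            raise ValueError("SUVr pair must share a grid")


def delta_suvr(pair: SUVrPair) -> TimeCourse:
    """Pointwise placebo-minus-challenge difference (the dopamine proxy)."""
    return TimeCourse(pair.placebo.grid,
                      pair.placebo.values - pair.challenge.values,
                      "delta_suvr")


def add_noise(tc: TimeCourse, cv: float, rng, mode: str = "multiplicative") -> TimeCourse:
    """Gaussian measurement noise on a curve.

    ``multiplicative`` (default): value * (1 + N(0, cv)) — cv is a
    coefficient of variation.  ``additive``: value + N(0, cv) with cv in the
    curve's units.  ``rng`` is a seed or a numpy Generator; results are
    reproducible for a fixed seed.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return tc
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    eps = cv * gen.standard_normal(tc.values.shape)
    if mode == "multiplicative":
        vals = tc.values * (1.0 + eps)
    elif mode == "additive":
        vals = tc.values + eps
    else:
        raise ValueError("mode must be 'multiplicative' or 'additive'")
    return tc.with_values(vals)


def resample_to_frames(tc: TimeCourse, frames: TimeGrid) -> TimeCourse:
    """Frame values as time-averages of the source curve within each frame.

    The source is treated as piecewise linear between samples.  Frames must
    lie inside the span of the source grid.
    """
    if frames.frame_bounds is None:
        raise ValueError("target grid must carry frame bounds")
    if tc.grid.frame_bounds is not None and \
            tc.grid.frame_bounds.shape == frames.frame_bounds.shape and \
            np.allclose(tc.grid.frame_bounds, frames.frame_bounds):
        return TimeCourse(frames, tc.values.copy(), tc.label)
    lo, hi = tc.grid.span
    fb = frames.frame_bounds
    if fb[0, 0] < lo - 1e-9 or fb[-1, 1] > hi + 1e-9:
        raise ValueError("frames extend outside the source grid span")
    out = np.empty(len(frames))
    for i, (a, b) in enumerate(fb):
        # dense trapezoid over the frame; includes interior source samples
        inner = tc.times[(tc.times > a) & (tc.times < b)]
        xs = np.concatenate([[a], inner, [b]])
        ys = tc.interp(xs)
        out[i] = np.trapezoid(ys, xs) / (b - a)
    return TimeCourse(frames, out, tc.label)
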