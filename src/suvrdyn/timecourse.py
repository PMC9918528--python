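"""Time grids and sampled time courses.

All times are minutes post tracer injection (t = 0 at the radiotracer bolus).
A :class:`TimeGrid` holds sample times (frame midpoints when the grid
represents an acquisition framing) and, optionally, explicit frame bounds.
A :class:`TimeCourse` is a grid plus values: plasma activity, a tissue TAC
(Bq/ml), or a dimensionless ratio such as SUVr.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeGrid", "TimeCourse", "default_grid", "pet_frame_grid"]

#: canonical scan duration (minutes)
SCAN_END = 90.0


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing sample times, optionally with frame bounds.

    Parameters
    ----------
    times :
        Sample times in minutes (frame midpoints for framed data).
    frame_bounds :
        Optional ``(n, 2)`` array of frame start/end times in minutes.
    """

    times: np.ndarray
    frame_bounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("grid needs at least two sample times")
        if not np.all(np.diff(t) > 0):
            raise ValueError("grid times must be strictly increasing")
        if self.frame_bounds is not None:
            fb = np.asarray(self.frame_bounds, dtype=float)
            object.__setattr__(self, "frame_bounds", fb)
            if fb.shape != (t.size, 2):
                raise ValueError("frame_bounds must be (n, 2)")
            if np.any(fb[:, 1] <= fb[:, 0]):
                raise ValueError("all frame durations must be positive")
            if not np.all(np.diff(fb[:, 0]) > 0):
                raise ValueError("frame starts must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> tuple[float, float]:
        if self.frame_bounds is not None:
            return float(self.frame_bounds[0, 0]), float(self.frame_bounds[-1, 1])
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class TimeCourse:
    """Values sampled on a :class:`TimeGrid`.

    ``label`` tags the role of the curve (``plasma``, ``reference``,
    ``target``, ``suvr``, ``delta_suvr``, ``h`` ...); it is metadata only.
    """

    grid: TimeGrid
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != self.grid.times.shape:
            raise ValueError("values length must equal grid length")

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeCourse":
        return TimeCourse(self.grid, values, self.label if label is None else label)

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation, clamped at the ends."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)


def default_grid(t_end: float = SCAN_END, dt: float = 1.0) -> TimeGrid:
    """Uniform sampling at frame midpoints (default 1-min frames over 0-90).

    The 1-min default matches the temporal resolution at which the dynamic
    SUVr difference is analysed.
    """
    n = int(round(t_end / dt))
    starts = dt * np.arange(n)
    bounds = np.column_stack([starts, starts + dt])
    return TimeGrid(starts + dt / 2, bounds)


def pet_frame_grid() -> TimeGrid:
    """The acquisition framing: 30 x 1 min, 12 x 2.5 min, 6 x 5 min (48 frames)."""
    durations = np.concatenate([np.full(30, 1.0), np.full(12, 2.5), np.full(6, 5.0)])
    ends = np.cumsum(durations)
    starts = ends - durations
    return TimeGrid((starts + ends) / 2, np.column_stack([starts, ends]))
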