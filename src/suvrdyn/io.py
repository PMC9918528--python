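"""Tabular TAC/SUVr I/O, JSON run configuration, fixture generation.

TAC tables are tab-separated text with a ``time_start_min``/``time_end_min``
pair followed by one value column per curve; ``#``-prefixed header lines
carry free-form metadata.  Writers emit deterministic byte streams (fixed
column order, 6 significant digits).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import batch
from .params import MPPlasmaParams
from .timecourse import TimeCourse, TimeGrid, default_grid

__all__ = ["read_tac_table", "write_tac_table", "RunConfig",
           "generate_fixture", "FIXTURE_SCENARIOS"]


def write_tac_table(path, curves: dict[str, TimeCourse],
                    metadata: dict | None = None) -> None:
    """Write one or more curves sharing a grid to a tab-separated table."""
    names = list(curves)
    first = curves[names[0]]
    for name in names[1:]:
        if not np.allclose(curves[name].times, first.times):
            raise ValueError("all curves in one table must share a grid")
    grid = first.grid
    if grid.frame_bounds is None:
        dt = np.diff(grid.times)
        half = np.concatenate([[dt[0]], dt]) / 2.0
        starts, ends = grid.times - half, grid.times + half
    else:
        starts, ends = grid.frame_bounds[:, 0], grid.frame_bounds[:, 1]
    lines = []
    for k, v in (metadata or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append("\t".join(["time_start_min", "time_end_min"] + names))
    for i in range(len(grid)):
        row = [f"{starts[i]:.6g}", f"{ends[i]:.6g}"]
        row += [f"{curves[n].values[i]:.6g}" for n in names]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_tac_table(path) -> dict[str, TimeCourse]:
    """Parse a TAC table; returns one TimeCourse per value column.

    Malformed rows, non-monotone frames and negative durations are reported
    with their line numbers.
    """
    text = Path(path).read_text().splitlines()
    header = None
    rows = []
    for lineno, line in enumerate(text, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if header is None:
            if parts[:2] != ["time_start_min", "time_end_min"]:
                raise ValueError(
                    f"line {lineno}: expected header starting with "
                    "time_start_min\ttime_end_min")
            header = parts
            continue
        if len(parts) != len(header):
            raise ValueError(f"line {lineno}: expected {len(header)} columns, "
                             f"got {len(parts)}")
        try:
            rows.append(([float(x) for x in parts], lineno))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric value") from exc
    if header is None or not rows:
        raise ValueError("table has no data rows")
    data = np.array([r[0] for r in rows])
    linenos = [r[1] for r in rows]
    starts, ends = data[:, 0], data[:, 1]
    for i in range(len(rows)):
        if ends[i] <= starts[i]:
            raise ValueError(f"line {linenos[i]}: non-positive frame duration")
        if i and starts[i] <= starts[i - 1]:
            raise ValueError(f"line {linenos[i]}: frames out of order")
    grid = TimeGrid((starts + ends) / 2.0, np.column_stack([starts, ends]))
    return {name: TimeCourse(grid, data[:, 2 + j], name)
            for j, name in enumerate(header[2:])}


@dataclass
class RunConfig:
    """Scenario configuration; round-trips losslessly through JSON."""

    scenario: str = "IV_PAPER"
    seed: int = 0
    noise_cv: float = 0.03
    noise_mode: str = "multiplicative"
    dose_scale: float = 1.0
    grid: str = "uniform_1min"   # or "pet_framing"
    overrides: dict = field(default_factory=dict)

    _KNOWN = ("scenario", "seed", "noise_cv", "noise_mode", "dose_scale",
              "grid", "overrides")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        unknown = set(d) - set(cls._KNOWN)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


FIXTURE_SCENARIOS = ("IV_PAPER", "ORAL_PAPER", "PLACEBO", "NOISY_PAIR")


def generate_fixture(scenario: str, seed: int, outdir) -> list[Path]:
    """Write a paired placebo/challenge SUVr+TAC fixture for a scenario.

    Scenarios: IV_PAPER (canonical IV challenge, noiseless), ORAL_PAPER
    (canonical oral challenge, noiseless), PLACEBO (both scans unchallenged),
    NOISY_PAIR (IV challenge with 3% SUVr noise).  Deterministic per seed.
    """
    scenario = scenario.upper()
    if scenario not in FIXTURE_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid: "
                         f"{', '.join(FIXTURE_SCENARIOS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = default_grid()
    rng = np.random.default_rng(seed)
    noise_cv = 0.03 if scenario == "NOISY_PAIR" else 0.0
    plasma = MPPlasmaParams.oral() if scenario == "ORAL_PAPER" else MPPlasmaParams()
    occ = batch.nominal_occupancy_arrays(1, plasma=plasma)
    if scenario == "PLACEBO":
        occ["dose_scale"] = np.zeros(1)
    scan = batch.nominal_scan_arrays(1)
    delta, _, s_pl, s_mp = batch.simulate_pair_batch(
        grid.times, scan, dict(scan), occ,
        noise_cv=noise_cv, rng=rng)
    cfg = RunConfig(scenario=scenario, seed=seed, noise_cv=noise_cv)
    files = []
    suvr_path = outdir / f"{scenario.lower()}_suvr.tsv"
    write_tac_table(suvr_path, {
        "suvr_placebo": TimeCourse(grid, s_pl[0], "suvr"),
        "suvr_challenge": TimeCourse(grid, s_mp[0], "suvr"),
        "delta_suvr": TimeCourse(grid, delta[0], "delta_suvr"),
    }, metadata={"scenario": scenario, "seed": seed, "units": "ratio"})
    files.append(suvr_path)
    cfg_path = outdir / f"{scenario.lower()}_config.json"
    cfg_path.write_text(cfg.to_json() + "\n")
    files.append(cfg_path)
    return files
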