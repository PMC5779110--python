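"""Tabular readers/writers and run configuration.

Input tables are delimited text with a header row (comma-separated by
default; tab-separated files are auto-detected): ROI intensity traces as a
``time``/``frame`` column plus one column per ROI, trajectories as
``time``/``frame`` + ``x`` + ``y``, heating observations as ``density`` +
``rate`` + ``context``. Output columns carry units in their names
(``speed_mm_per_s``) to prevent unit drift. Run configurations are
JSON/YAML key-value files, echoed verbatim into the output directory so
every run is reproducible from its own record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import Trajectory
from .physics import HeatingObservation
from .thermometry import FluorescenceTrace

__all__ = [
    "RunConfig",
    "read_table",
    "read_trace_table",
    "read_trajectory_table",
    "read_trajectory_segments",
    "read_heating_table",
    "write_heating_table",
    "read_config",
    "write_config",
]


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run: inputs, stage parameter
    overrides, seed and output directory; fully serializable."""

    inputs: dict = dc_field(default_factory=dict)
    parameters: dict = dc_field(default_factory=dict)
    seed: int = 0
    output_dir: str = "results"

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "parameters": self.parameters,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            inputs=dict(d.get("inputs", {})),
            parameters=dict(d.get("parameters", {})),
            seed=int(d.get("seed", 0)),
            output_dir=str(d.get("output_dir", "results")),
        )


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table with a header row; the delimiter (comma
    or tab) is auto-detected from the header line."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _time_column(
    df: pd.DataFrame, path: Path, fs: float | None
) -> np.ndarray:
    if "time" in df.columns:
        time = df["time"].to_numpy(dtype=float)
    elif "frame" in df.columns:
        if fs is None:
            raise ValueError(
                f"{path}: frame-indexed table requires a sample rate (fs)"
            )
        time = df["frame"].to_numpy(dtype=float) / fs
    else:
        raise ValueError(f"{path}: need a 'time' or 'frame' column")
    if np.any(np.diff(time) <= 0):
        bad = int(np.flatnonzero(np.diff(time) <= 0)[0]) + 1
        raise ValueError(f"{path}: non-increasing time at row {bad}")
    dt = np.diff(time)
    if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
        bad = int(np.flatnonzero(~np.isclose(dt, dt[0], rtol=1e-4))[0]) + 1
        raise ValueError(f"{path}: non-uniform time step at row {bad}")
    return time


def read_trace_table(
    path: str | Path, fs: float | None = 10.0, dark_noise: float = 0.0
) -> list[FluorescenceTrace]:
    """Read ROI mean-intensity traces from a delimited table.

    One column named ``time`` (s) or ``frame`` (converted via ``fs``), and
    one numeric column per ROI. Returns one trace per ROI column.
    """
    path = Path(path)
    df = read_table(path)
    time = _time_column(df, path, fs)
    roi_cols = [c for c in df.columns if c not in ("time", "frame")]
    if not roi_cols:
        raise ValueError(f"{path}: no ROI intensity columns found")
    traces = []
    for col in roi_cols:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        if np.any(np.isnan(vals)):
            bad = int(np.flatnonzero(np.isnan(vals))[0]) + 1
            raise ValueError(f"{path}: non-numeric cell in '{col}' row {bad}")
        traces.append(
            FluorescenceTrace(time=time, intensity=vals, dark_noise=dark_noise,
                              roi=col)
        )
    return traces


def read_trajectory_table(
    path: str | Path,
    fs: float | None = 30.0,
    scale_mm_per_px: float | None = None,
    every_nth_frame: int = 1,
    arena_center: tuple[float, float] = (0.0, 0.0),
    arena_radius: float = 50.0,
    max_gap_s: float = 0.5,
) -> Trajectory:
    """Read a marker trajectory from a delimited table.

    Columns: ``time`` (s) or ``frame``, plus ``x`` and ``y``. Pixel
    coordinates are converted with ``scale_mm_per_px``; ``every_nth_frame``
    declares pre-decimation of a higher-rate video (e.g. every second frame
    of 60 fps footage giving 30 samples/s). Tracking dropouts (empty x/y
    cells) up to ``max_gap_s`` are filled by linear interpolation; a longer
    dropout raises — use :func:`read_trajectory_segments` to split such a
    record instead. Points far outside the arena raise with their row
    indices.
    """
    segments = read_trajectory_segments(
        path, fs=fs, scale_mm_per_px=scale_mm_per_px,
        every_nth_frame=every_nth_frame, arena_center=arena_center,
        arena_radius=arena_radius, max_gap_s=max_gap_s,
    )
    if len(segments) != 1:
        raise ValueError(
            f"{path}: a tracking dropout longer than {max_gap_s} s splits the "
            f"record into {len(segments)} segments; use "
            "read_trajectory_segments"
        )
    return segments[0]


def read_trajectory_segments(
    path: str | Path,
    fs: float | None = 30.0,
    scale_mm_per_px: float | None = None,
    every_nth_frame: int = 1,
    arena_center: tuple[float, float] = (0.0, 0.0),
    arena_radius: float = 50.0,
    max_gap_s: float = 0.5,
) -> list[Trajectory]:
    """Like :func:`read_trajectory_table`, but dropouts longer than
    ``max_gap_s`` split the record; returns the contiguous segments."""
    path = Path(path)
    df = read_table(path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing '{col}' column")
    eff_fs = None if fs is None else fs / every_nth_frame
    time = _time_column(df, path, eff_fs)
    x = pd.to_numeric(df["x"], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df["y"], errors="coerce").to_numpy(dtype=float)
    for name, raw, vals in (("x", df["x"], x), ("y", df["y"], y)):
        bad = np.isnan(vals) & raw.notna().to_numpy() \
            & (raw.astype(str).str.strip() != "").to_numpy()
        if np.any(bad):
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(f"{path}: non-numeric cell in '{name}' row {row}")
    if scale_mm_per_px is not None:
        x = x * scale_mm_per_px
        y = y * scale_mm_per_px

    missing = np.isnan(x) | np.isnan(y)
    dt = float(time[1] - time[0])
    max_gap = max(1, int(round(max_gap_s / dt)))
    segments: list[Trajectory] = []
    idx = np.arange(time.size)
    for lo, hi in _long_gap_bounds(missing, max_gap, time.size):
        if hi - lo >= 2:
            segments.append(_build_segment(
                path, time[lo:hi], x[lo:hi], y[lo:hi], missing[lo:hi],
                idx[lo:hi], arena_center, arena_radius,
            ))
    return segments


def _long_gap_bounds(missing, max_gap, n):
    """Yield (start, stop) index ranges between dropout runs > max_gap."""
    bounds = []
    run_start = None
    cut_points = []
    for i in range(n):
        if missing[i]:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start > max_gap:
                cut_points.append((run_start, i))
            run_start = None
    if run_start is not None and n - run_start > max_gap:
        cut_points.append((run_start, n))
    prev = 0
    for lo, hi in cut_points:
        bounds.append((prev, lo))
        prev = hi
    bounds.append((prev, n))
    return [(lo, hi) for lo, hi in bounds if hi > lo]


def _build_segment(path, time, x, y, missing, idx, arena_center, arena_radius):
    if np.any(missing):  # short dropouts: linear interpolation
        ok = ~missing
        x = x.copy()
        y = y.copy()
        x[missing] = np.interp(time[missing], time[ok], x[ok])
        y[missing] = np.interp(time[missing], time[ok], y[ok])
    r = np.hypot(x - arena_center[0], y - arena_center[1])
    outside = np.flatnonzero(r > 1.1 * arena_radius)
    if outside.size:
        rows = ", ".join(map(str, (idx[outside] + 1)[:10]))
        raise ValueError(
            f"{path}: {outside.size} points outside the arena (rows {rows})"
        )
    return Trajectory(
        time=time, x=x, y=y, arena_center=arena_center,
        arena_radius=arena_radius,
    )


def read_heating_table(path: str | Path) -> list[HeatingObservation]:
    """Read heating observations (columns density, rate, context)."""
    path = Path(path)
    df = read_table(path)
    for col in ("density", "rate"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing '{col}' column")
    context = df["context"] if "context" in df.columns else "suspension"
    if isinstance(context, str):
        context = [context] * len(df)
    return [
        HeatingObservation(density=float(d), rate=float(r), context=str(c))
        for d, r, c in zip(df["density"], df["rate"], context)
    ]


def write_heating_table(
    observations: list[HeatingObservation], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "density": [o.density for o in observations],
            "rate": [o.rate for o in observations],
            "context": [o.context for o in observations],
        }
    )
    df.to_csv(path, index=False)


def read_config(path: str | Path) -> RunConfig:
    """Read a run configuration from a JSON or YAML file (by extension; YAML
    parses JSON too, so unknown extensions fall back to YAML)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return RunConfig.from_dict(data)


def write_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(config.to_dict()), encoding="utf-8")
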