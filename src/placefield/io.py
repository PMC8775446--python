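"""Readers and writers for the pipeline's tabular formats.

Traces: HDF5 (dataset "traces", attrs fps/cell_ids) or wide CSV.
Trajectory, events, match tables: CSV via pandas.  All tables round-trip
and are schema-validated with errors that name the offending column.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .events import CalciumEvent, TraceMatrix
from .sessions import CellMatch
from .synthetic import TrackGeometry, Trajectory

__all__ = [
    "write_traces_h5", "read_traces_h5",
    "write_traces_csv", "read_traces_csv",
    "write_trajectory_csv", "read_trajectory_csv",
    "write_events_csv", "read_events_csv",
    "write_match_csv", "read_match_csv",
    "write_geometry_json", "read_geometry_json",
    "write_json", "read_json",
]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def write_traces_h5(path: str | Path, tm: TraceMatrix) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("traces", data=tm.values)
        d.attrs["fps"] = tm.fps
        f.create_dataset("cell_ids", data=np.asarray(tm.cell_ids, dtype=np.int64))


def read_traces_h5(path: str | Path) -> TraceMatrix:
    with h5py.File(path, "r") as f:
        if "traces" not in f:
            raise ValueError("traces HDF5: missing dataset 'traces'")
        values = f["traces"][...]
        if "fps" not in f["traces"].attrs:
            raise ValueError("traces HDF5: missing attribute 'fps'")
        fps = float(f["traces"].attrs["fps"])
        cell_ids = f["cell_ids"][...] if "cell_ids" in f else None
    return TraceMatrix(values=values, fps=fps, cell_ids=cell_ids)


def write_traces_csv(path: str | Path, tm: TraceMatrix) -> None:
    df = pd.DataFrame(tm.values.T, columns=[f"cell_{int(c)}" for c in tm.cell_ids])
    df.insert(0, "t", tm.times)
    df.to_csv(path, index=False, float_format="%.9g")
    # fps is recoverable from the time column on read


def read_traces_csv(path: str | Path) -> TraceMatrix:
    df = pd.read_csv(path)
    _require_columns(df, ["t"], "traces CSV")
    cols = [c for c in df.columns if c.startswith("cell_")]
    if not cols:
        raise ValueError("traces CSV: no 'cell_*' columns found")
    t = df["t"].to_numpy()
    if t.size < 2:
        raise ValueError("traces CSV: need at least 2 frames")
    fps = 1.0 / float(np.median(np.diff(t)))
    ids = np.array([int(c.split("_", 1)[1]) for c in cols])
    return TraceMatrix(values=df[cols].to_numpy().T, fps=fps, cell_ids=ids)


def write_trajectory_csv(path: str | Path, traj: Trajectory) -> None:
    pd.DataFrame(
        {"t": traj.t, "x": traj.x, "y": traj.y, "theta": traj.theta,
         "speed": traj.speed}
    ).to_csv(path, index=False, float_format="%.9g")


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    _require_columns(df, ["t", "x", "y", "theta"], "trajectory CSV")
    t = df["t"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trajectory CSV: need at least 2 samples")
    fps = 1.0 / float(np.median(np.diff(t)))
    speed = df["speed"].to_numpy(dtype=float) if "speed" in df else np.full(t.size, np.nan)
    return Trajectory(
        t=t, x=df["x"].to_numpy(float), y=df["y"].to_numpy(float),
        theta=df["theta"].to_numpy(float), speed=speed, fps=fps,
    )


EVENT_COLUMNS = ["cell_id", "t0", "A", "t_on", "t_off", "gof"]


def write_events_csv(path: str | Path, events: list[CalciumEvent]) -> None:
    pd.DataFrame(
        [{c: getattr(e, c) for c in EVENT_COLUMNS} for e in events],
        columns=EVENT_COLUMNS,
    ).to_csv(path, index=False, float_format="%.9g")


def read_events_csv(path: str | Path) -> list[CalciumEvent]:
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, "events CSV")
    by_cell = df.groupby("cell_id", sort=True)
    out: list[CalciumEvent] = []
    warned = False
    for cid, grp in by_cell:
        t0 = grp["t0"].to_numpy()
        if np.any(np.diff(t0) < 0) and not warned:
            warnings.warn("events CSV had unsorted t0; sorted on read",
                          RuntimeWarning, stacklevel=2)
            warned = True
        grp = grp.sort_values("t0")
        for row in grp.itertuples(index=False):
            out.append(CalciumEvent(int(row.cell_id), float(row.t0), float(row.A),
                                    float(row.t_on), float(row.t_off), float(row.gof)))
    return out


def write_match_csv(path: str | Path, match: CellMatch) -> None:
    pd.DataFrame(match.pairs, columns=["cell_a", "cell_b"]).to_csv(path, index=False)


def read_match_csv(path: str | Path) -> CellMatch:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_a", "cell_b"], "match CSV")
    return CellMatch(tuple((int(a), int(b)) for a, b in
                           zip(df["cell_a"], df["cell_b"])))


def write_geometry_json(path: str | Path, geom: TrackGeometry) -> None:
    Path(path).write_text(json.dumps(
        {"outer_diameter": geom.outer_diameter, "width": geom.width,
         "n_bins": geom.n_bins}, indent=2))


def read_geometry_json(path: str | Path) -> TrackGeometry:
    data = json.loads(Path(path).read_text())
    return TrackGeometry(**data)


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
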