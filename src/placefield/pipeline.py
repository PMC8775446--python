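"""End-to-end session analysis: events -> place fields -> manifold -> report."""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import fields as pf
from . import io as pio
from . import manifold as mf
from .config import SessionConfig
from .events import SENSOR_PROFILES, CalciumEvent, TraceMatrix, detect_events_matrix
from .synthetic import TrackGeometry, Trajectory

__all__ = ["SessionReport", "run_pipeline", "records_by_cell", "session_summary"]


@dataclass
class SessionReport:
    """Headline statistics of one analysed session."""

    config_hash: str
    n_cells: int
    n_place_cells: int
    n_fields: int
    frac_first_attendance: float | None  # fields with n_spec == 0
    mean_nspec: float | None
    mean_tspec: float | None  # seconds
    mean_selectivity_by_visit: list[float] = field(default_factory=list)
    rv_global: float | None = None
    rv_sliding: list[dict] = field(default_factory=list)
    fields_table: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def records_by_cell(
    events: list[CalciumEvent],
    traj: Trajectory,
    geometry: TrackGeometry,
    cfg: SessionConfig,
) -> dict[int, list[pf.SelectivityRecord]]:
    by_cell: dict[int, list[CalciumEvent]] = {}
    for e in events:
        by_cell.setdefault(e.cell_id, []).append(e)
    out = {}
    for cid, evs in sorted(by_cell.items()):
        out[cid] = pf.analyze_cell(
            evs, traj, geometry,
            sigma_bins=cfg.sigma_bins, map_threshold=cfg.map_threshold,
            score_sigma=cfg.score_sigma, score_threshold=cfg.score_threshold,
            min_run=cfg.min_relevant_run, debounce=cfg.debounce_s,
        )
    return out


def _mean_selectivity_by_visit(records: list[pf.SelectivityRecord]) -> list[float]:
    """Mean raw score across fields for each visit index (1st, 2nd, ...)."""
    max_v = max((r.scored_idx.size for r in records), default=0)
    out = []
    for v in range(max_v):
        vals = [r.raw_scores[r.scored_idx[v]] for r in records if r.scored_idx.size > v]
        out.append(float(np.mean(vals)))
    return out


def session_summary(records: dict[int, list[pf.SelectivityRecord]]) -> dict:
    """Per-field center/latency summary consumed by session comparison."""
    centers: dict[int, list[float]] = {}
    nspec: dict[int, int] = {}
    for cid, recs in records.items():
        pcs = [r for r in recs if r.is_place_cell]
        if pcs:
            centers[cid] = [r.field.center_bin for r in pcs]
            if len(pcs) == 1:
                nspec[cid] = int(pcs[0].n_spec)
    return {"centers": centers, "nspec": nspec}


def run_pipeline(
    cfg: SessionConfig,
    traces: TraceMatrix,
    traj: Trajectory,
    events: list[CalciumEvent] | None = None,
    out_dir: str | Path | None = None,
) -> SessionReport:
    """detect-events -> place-fields -> embed -> rv, deterministic given cfg.

    ``events`` may be supplied to skip the detection stage (e.g. when the
    events CSV already exists).
    """
    geometry = TrackGeometry(cfg.outer_diameter, cfg.width, cfg.n_bins)
    if events is None:
        profile = SENSOR_PROFILES[cfg.sensor]
        events = detect_events_matrix(traces, profile, gof_min=cfg.gof_min)

    rec_map = records_by_cell(events, traj, geometry, cfg)
    place_records = [r for recs in rec_map.values() for r in recs if r.is_place_cell]
    nspecs = np.array([r.n_spec for r in place_records], dtype=float)
    tspecs = np.array([r.t_spec for r in place_records], dtype=float)

    rv_global = None
    rv_sliding: list[dict] = []
    try:
        X = mf.prepare_activity(traces, events, cfg.w, cfg.min_events)
        G = mf.build_graph(X, cfg.k) if cfg.k else mf.choose_k(X)
        emb = mf.laplacian_eigenmaps(G, cfg.m)
        pos = mf.window_positions(traj, cfg.w)[: X.n_windows][G.kept_nodes]
        rv_global = mf.residual_variance(pos, emb).rv
        for r in mf.sliding_rv(X, mf.window_positions(traj, cfg.w)[: X.n_windows],
                               k=G.k, m=cfg.m, window_s=cfg.rv_window_s,
                               stride_s=cfg.rv_stride_s):
            rv_sliding.append({"t_center": r.t_center, "rv": r.rv, "n": r.n})
    except (ValueError, mf.GraphDisconnectedError) as exc:
        warnings.warn(f"manifold stage skipped: {exc}", RuntimeWarning, stacklevel=2)

    n_pc_cells = sum(1 for recs in rec_map.values() if any(r.is_place_cell for r in recs))
    report = SessionReport(
        config_hash=cfg.config_hash,
        n_cells=traces.n_cells,
        n_place_cells=n_pc_cells,
        n_fields=len(place_records),
        frac_first_attendance=(float(np.mean(nspecs == 0)) if nspecs.size else None),
        mean_nspec=(float(nspecs.mean()) if nspecs.size else None),
        mean_tspec=(float(tspecs.mean()) if tspecs.size else None),
        mean_selectivity_by_visit=_mean_selectivity_by_visit(place_records),
        rv_global=rv_global,
        rv_sliding=rv_sliding,
        fields_table=[
            {
                "cell_id": r.field.cell_id,
                "center_bin": round(r.field.center_bin, 6),
                "width_bins": r.field.width_bins,
                "start_bin": r.field.bins[0],
                "n_spec": r.n_spec,
                "t_spec": None if r.t_spec is None else round(r.t_spec, 6),
            }
            for recs in rec_map.values() for r in recs if r.is_place_cell
        ],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_events_csv(out / "events.csv", events)
        pio.write_json(out / "report.json", report.to_dict())
        (out / "config.json").write_text(cfg.to_json())
    return report
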