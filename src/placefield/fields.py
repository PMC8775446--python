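"""Place-field detection, per-attendance selectivity, and tuning latency.

The track is divided into 20 sectorial bins.  The spatial distribution of
a cell's calcium events is smoothed with a circular Gaussian kernel
(sigma = 1.25 bins) and peak-normalized; contiguous runs of bins above
0.5 are putative fields, widened by one bin on each side, and fields
wider than half the track are excluded.  Per attendance of a field the
selectivity score is the fraction of the cell's events falling inside
the attendance epoch relative to events in the epoch plus its flanking
out-of-field intervals.  The score sequence is smoothed (Gaussian,
sigma = 1 in visit units); a field is confirmed iff it has a run of at
least three consecutive relevant visits (smoothed score > 0.5), and the
tuning latency is the visit count (n_spec) / time (t_spec) before that
run begins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .events import CalciumEvent
from .synthetic import TrackGeometry, Trajectory

__all__ = [
    "SpatialEventMap",
    "PlaceField",
    "AttendanceEpoch",
    "SelectivityRecord",
    "gaussian_smooth",
    "bin_events",
    "smooth_normalize",
    "detect_fields",
    "attendances",
    "selectivity_score",
    "classify_and_latency",
    "analyze_cell",
]

MAP_SIGMA_BINS = 1.25
SCORE_SIGMA = 1.0
MAP_THRESHOLD = 0.5
SCORE_THRESHOLD = 0.5
MIN_RELEVANT_RUN = 3
DEBOUNCE_S = 1.0


@dataclass
class SpatialEventMap:
    """Event counts per track bin, optionally smoothed and peak-normalized."""

    cell_id: int
    bin_counts: np.ndarray  # ints, length n_bins, circular
    smoothed: np.ndarray | None = None  # in [0, 1], max 1 where events exist


@dataclass(frozen=True)
class PlaceField:
    """A contiguous circular interval of track bins owned by one cell."""

    cell_id: int
    center_bin: float  # circular centroid in bin units, in [0, n_bins)
    bins: tuple[int, ...]  # expanded contiguous interval (circular)
    width_bins: int
    n_bins: int

    @property
    def center_theta(self) -> float:
        return self.center_bin * 2.0 * np.pi / self.n_bins


@dataclass(frozen=True)
class AttendanceEpoch:
    """One visit to a place field with its flanking out-of-field intervals."""

    index: int  # 1-based visit number
    t_enter: float
    t_exit: float
    flank_before: tuple[float, float]
    flank_after: tuple[float, float]


@dataclass
class SelectivityRecord:
    """Per-field selectivity history and the latency verdict."""

    field: PlaceField
    epochs: list[AttendanceEpoch]
    raw_scores: np.ndarray  # per epoch; NaN where scoreless (no events at all)
    scored_idx: np.ndarray  # indices into epochs of non-NaN scores
    smoothed_scores: np.ndarray  # aligned with scored_idx
    relevant: np.ndarray  # bool, aligned with scored_idx
    is_place_cell: bool
    n_spec: int | None  # attendances before the first >=3-relevant run
    t_spec: float | None  # t_enter of the first epoch of that run


def gaussian_smooth(x: np.ndarray, sigma: float, mode: str = "reflect") -> np.ndarray:
    """Truncated-Gaussian smoothing with explicit padding.

    ``mode="reflect"`` pads symmetrically (a b c | c b a); ``mode="wrap"``
    pads circularly.  Kernel radius is int(4*sigma + 0.5), matching the
    usual 4-sigma truncation.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    if sigma <= 0:
        return x.copy()
    r = int(4.0 * sigma + 0.5)
    if r == 0:
        return x.copy()
    k = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    k /= k.sum()
    pad_mode = "symmetric" if mode == "reflect" else "wrap"
    padded = np.pad(x, r, mode=pad_mode)
    return np.convolve(padded, k, mode="valid")


def bin_events(
    events: list[CalciumEvent], traj: Trajectory, geometry: TrackGeometry
) -> SpatialEventMap:
    """Assign each event to the sectorial bin of the interpolated position at t0."""
    counts = np.zeros(geometry.n_bins, dtype=int)
    cell_id = events[0].cell_id if events else -1
    if events:
        t0s = np.array([e.t0 for e in events])
        if t0s.min() < traj.t[0] - 1e-9 or t0s.max() > traj.t[-1] + 1.0 / traj.fps:
            raise ValueError("event time outside trajectory range")
        bins = geometry.bin_of(traj.theta_at(t0s))
        np.add.at(counts, bins, 1)
    return SpatialEventMap(cell_id=cell_id, bin_counts=counts)


def smooth_normalize(
    emap: SpatialEventMap, sigma_bins: float = MAP_SIGMA_BINS
) -> SpatialEventMap:
    """Circular Gaussian smoothing then division by the maximum (peak = 1)."""
    counts = np.asarray(emap.bin_counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("cannot smooth a map with no events")
    sm = gaussian_filter1d(counts, sigma_bins, mode="wrap")
    emap.smoothed = sm / sm.max()
    return emap


def _circular_runs(mask: np.ndarray) -> list[np.ndarray]:
    """Maximal contiguous runs of True on a circular index set."""
    n = mask.size
    if mask.all():
        return [np.arange(n)]
    if not mask.any():
        return []
    # rotate so position 0 is False, then find linear runs
    start = int(np.flatnonzero(~mask)[0])
    rolled = np.roll(mask, -start)
    runs = []
    idx = np.flatnonzero(rolled)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for s in splits:
        runs.append(np.mod(s + start, n))
    return runs


def _circular_centroid(bins: np.ndarray, weights: np.ndarray, n_bins: int) -> float:
    ang = (bins + 0.5) * 2.0 * np.pi / n_bins
    z = np.sum(weights * np.exp(1j * ang))
    c = np.mod(np.angle(z), 2.0 * np.pi)
    return float(np.mod(c / (2.0 * np.pi) * n_bins - 0.5, n_bins))


def detect_fields(
    emap: SpatialEventMap,
    geometry: TrackGeometry,
    threshold: float = MAP_THRESHOLD,
) -> list[PlaceField]:
    """Putative fields = above-threshold peaks of the normalized map,
    widened by 1 bin each side; fields wider than half the track excluded."""
    if emap.smoothed is None:
        raise ValueError("map must be smoothed first (smooth_normalize)")
    n = geometry.n_bins
    mask = emap.smoothed > threshold
    fields = []
    for run in _circular_runs(mask):
        width = run.size + 2
        if width > n // 2 or run.size == n:
            continue  # wider than half the track (or the whole circle)
        center = _circular_centroid(run, emap.smoothed[run], n)
        lo = run[0] - 1
        expanded = tuple(int(np.mod(lo + j, n)) for j in range(width))
        fields.append(
            PlaceField(
                cell_id=emap.cell_id, center_bin=center, bins=expanded,
                width_bins=width, n_bins=n,
            )
        )
    fields.sort(key=lambda f: f.center_bin)
    return fields


def attendances(
    traj: Trajectory,
    field: PlaceField,
    geometry: TrackGeometry,
    debounce: float = DEBOUNCE_S,
) -> list[AttendanceEpoch]:
    """Maximal in-field time intervals with their flanking intervals.

    Out-of-field excursions shorter than ``debounce`` seconds do not split
    an epoch (positional jitter at bin edges would otherwise fragment
    visits).  Intervals are half-open [enter, exit).
    """
    in_field = np.isin(geometry.bin_of(traj.theta), field.bins)
    if not in_field.any():
        return []
    dt = 1.0 / traj.fps
    d = np.diff(in_field.astype(int))
    enters = list(np.flatnonzero(d == 1) + 1)
    exits = list(np.flatnonzero(d == -1) + 1)  # first out-of-field frame
    if in_field[0]:
        enters.insert(0, 0)
    if in_field[-1]:
        exits.append(traj.t.size)
    intervals = [[traj.t[a], traj.t[b] if b < traj.t.size else traj.t[-1] + dt]
                 for a, b in zip(enters, exits)]
    # merge visits separated by gaps shorter than the debounce
    merged = [intervals[0]]
    for iv in intervals[1:]:
        if iv[0] - merged[-1][1] < debounce:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)

    t_start = traj.t[0]
    t_end = traj.t[-1] + dt
    epochs = []
    for i, (enter, exit_) in enumerate(merged):
        before = (merged[i - 1][1] if i > 0 else t_start, enter)
        after = (exit_, merged[i + 1][0] if i + 1 < len(merged) else t_end)
        epochs.append(
            AttendanceEpoch(
                index=i + 1, t_enter=float(enter), t_exit=float(exit_),
                flank_before=(float(before[0]), float(before[1])),
                flank_after=(float(after[0]), float(after[1])),
            )
        )
    return epochs


def selectivity_score(event_times: np.ndarray, epoch: AttendanceEpoch) -> float:
    """In-epoch events over events in epoch plus both flanks; NaN if none."""
    t = np.asarray(event_times, dtype=float)
    n_in = int(np.count_nonzero((t >= epoch.t_enter) & (t < epoch.t_exit)))
    fb, fa = epoch.flank_before, epoch.flank_after
    n_flank = int(
        np.count_nonzero((t >= fb[0]) & (t < fb[1]))
        + np.count_nonzero((t >= fa[0]) & (t < fa[1]))
    )
    denom = n_in + n_flank
    if denom == 0:
        return float("nan")
    return n_in / denom


def _first_run(mask: np.ndarray, min_len: int) -> int | None:
    """Start index of the first run of >= min_len consecutive True, else None."""
    count = 0
    for i, m in enumerate(mask):
        count = count + 1 if m else 0
        if count == min_len:
            return i - min_len + 1
    return None


def classify_and_latency(
    field: PlaceField,
    epochs: list[AttendanceEpoch],
    raw_scores: np.ndarray,
    sigma: float = SCORE_SIGMA,
    threshold: float = SCORE_THRESHOLD,
    min_run: int = MIN_RELEVANT_RUN,
) -> SelectivityRecord:
    """Smooth the score sequence, flag relevant visits, find the latency.

    Scoreless epochs (NaN raw score: the cell emitted no event anywhere on
    that lap) are excluded from the smoothed sequence; a silent lap is
    evidence of inactivity, not of non-selectivity.  n_spec counts all
    attendances (including scoreless ones) strictly before the first run
    of >= min_run consecutive relevant scored visits.
    """
    raw_scores = np.asarray(raw_scores, dtype=float)
    if raw_scores.size != len(epochs):
        raise ValueError("raw_scores must align with epochs")
    scored_idx = np.flatnonzero(~np.isnan(raw_scores))
    scored = raw_scores[scored_idx]
    if np.any((scored < 0) | (scored > 1)):
        raise ValueError("selectivity scores must lie in [0, 1]")
    smoothed = gaussian_smooth(scored, sigma, mode="reflect")
    relevant = smoothed > threshold
    run_start = _first_run(relevant, min_run) if scored.size else None
    if run_start is None:
        return SelectivityRecord(
            field=field, epochs=epochs, raw_scores=raw_scores,
            scored_idx=scored_idx, smoothed_scores=smoothed, relevant=relevant,
            is_place_cell=False, n_spec=None, t_spec=None,
        )
    first_epoch = epochs[int(scored_idx[run_start])]
    return SelectivityRecord(
        field=field, epochs=epochs, raw_scores=raw_scores,
        scored_idx=scored_idx, smoothed_scores=smoothed, relevant=relevant,
        is_place_cell=True, n_spec=first_epoch.index - 1,
        t_spec=first_epoch.t_enter,
    )


def analyze_cell(
    events: list[CalciumEvent],
    traj: Trajectory,
    geometry: TrackGeometry,
    sigma_bins: float = MAP_SIGMA_BINS,
    map_threshold: float = MAP_THRESHOLD,
    score_sigma: float = SCORE_SIGMA,
    score_threshold: float = SCORE_THRESHOLD,
    min_run: int = MIN_RELEVANT_RUN,
    debounce: float = DEBOUNCE_S,
) -> list[SelectivityRecord]:
    """Full per-cell pipeline: map -> fields -> attendances -> latency."""
    if not events:
        return []
    emap = bin_events(events, traj, geometry)
    if emap.bin_counts.sum() == 0:
        return []
    smooth_normalize(emap, sigma_bins)
    event_times = np.array([e.t0 for e in events])
    records = []
    for f in detect_fields(emap, geometry, map_threshold):
        eps = attendances(traj, f, geometry, debounce)
        if not eps:
            continue
        raw = np.array([selectivity_score(event_times, ep) for ep in eps])
        records.append(
            classify_and_latency(
                f, eps, raw, sigma=score_sigma, threshold=score_threshold,
                min_run=min_run,
            )
        )
    return records
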