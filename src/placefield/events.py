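"""Calcium-event detection from fluorescence traces.

Each trace is scanned for upward crossings of a robust (median + k*MAD)
threshold; the neighbourhood of every crossing is fitted with a
two-exponential transient model

    f(t) = A * (1 - exp(-(t - t0)/t_on)) * exp(-(t - t0)/t_off),   t >= t0

and, if the fit is acceptable (R^2 >= 0.8), the event is scored and the
fitted curve is locally subtracted from a working copy of the trace so
that overlapping transients can be resolved on subsequent passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

__all__ = [
    "TraceMatrix",
    "SensorProfile",
    "CalciumEvent",
    "SENSOR_PROFILES",
    "transient_kernel",
    "kernel_peak_time",
    "kernel_peak_gain",
    "mad_threshold",
    "fit_event",
    "detect_events",
    "detect_events_matrix",
    "is_acceptable_fit",
]

GOF_MIN = 0.8


@dataclass
class TraceMatrix:
    """Cells x frames fluorescence matrix with its frame rate."""

    values: np.ndarray  # (n_cells, n_frames), float
    fps: float
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x frames array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace matrix contains non-finite values")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.values.shape[0])
        else:
            self.cell_ids = np.asarray(self.cell_ids)
            if self.cell_ids.shape[0] != self.values.shape[0]:
                raise ValueError("cell_ids length must match number of rows")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class SensorProfile:
    """Detection constants for a calcium-sensor kinetics class.

    Slow sensors (GCaMP6s, NCaMP7, FGCaMP7) use a 4-MAD threshold and a
    0.5 s lower bound on the decay constant; the fast GCaMP7f uses 5 MADs
    and a 0.2 s decay floor.
    """

    name: str
    speed_class: str  # "slow" | "fast"
    mad_multiplier: int
    t_off_floor: float  # seconds

    def __post_init__(self) -> None:
        if self.speed_class not in ("slow", "fast"):
            raise ValueError("speed_class must be 'slow' or 'fast'")
        if self.mad_multiplier not in (4, 5):
            raise ValueError("mad_multiplier must be 4 (slow) or 5 (fast)")
        if self.t_off_floor <= 0:
            raise ValueError("t_off_floor must be positive")


SENSOR_PROFILES: dict[str, SensorProfile] = {
    "gcamp6s": SensorProfile("gcamp6s", "slow", 4, 0.5),
    "ncamp7": SensorProfile("ncamp7", "slow", 4, 0.5),
    "fgcamp7": SensorProfile("fgcamp7", "slow", 4, 0.5),
    "gcamp7f": SensorProfile("gcamp7f", "fast", 5, 0.2),
}


@dataclass(frozen=True)
class CalciumEvent:
    """One detected transient."""

    cell_id: int
    t0: float  # onset, seconds
    A: float  # amplitude prefactor, trace units
    t_on: float  # rise time constant, seconds
    t_off: float  # decay time constant, seconds
    gof: float  # R^2 of the accepted fit


def transient_kernel(dt: np.ndarray, t_on: float, t_off: float) -> np.ndarray:
    """Unit-amplitude transient (1 - e^(-dt/t_on)) e^(-dt/t_off), zero for dt < 0."""
    dt = np.asarray(dt, dtype=float)
    out = np.zeros_like(dt)
    pos = dt > 0
    d = dt[pos]
    out[pos] = (1.0 - np.exp(-d / t_on)) * np.exp(-d / t_off)
    return out


def kernel_peak_time(t_on: float, t_off: float) -> float:
    """Time after onset at which the unit kernel peaks: t_on * ln(1 + t_off/t_on)."""
    return t_on * np.log(1.0 + t_off / t_on)

def kernel_peak_gain(t_on: float, t_off: float) -> float:
    """Peak value of the unit-amplitude kernel (realised peak = A * gain)."""
    tp = kernel_peak_time(t_on, t_off)
    return float((1.0 - np.exp(-tp / t_on)) * np.exp(-tp / t_off))


def mad_threshold(trace: np.ndarray, multiplier: int) -> float:
    """median(trace) + multiplier * raw MAD (no normal-consistency factor)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace must have at least 2 samples")
    med = float(np.median(trace))
    mad = float(np.median(np.abs(trace - med)))
    if mad == 0.0:
        warnings.warn(
            "MAD is zero (trace is constant over >= half its samples); "
            "threshold degenerates to the median",
            RuntimeWarning,
            stacklevel=2,
        )
    return med + multiplier * mad


def is_acceptable_fit(gof: float, gof_min: float = GOF_MIN) -> bool:
    """An event is scored iff its goodness of fit reaches the 0.8 floor (inclusive)."""
    return gof >= gof_min


def _model(t, t0, A, t_on, t_off, b):
    return b + A * transient_kernel(t - t0, t_on, t_off)


def fit_event(
    segment: np.ndarray,
    times: np.ndarray,
    t0_init: float,
    profile: SensorProfile,
    baseline: float = 0.0,
):
    """Nonlinear least squares of the transient model on one segment.

    The model is the two-exponential kernel plus a free constant offset
    ``b`` (initialised at ``baseline``), which absorbs the local baseline
    elevation left by neighbouring transient tails.  Returns
    ``(params, gof)`` where ``params`` is ``{t0, A, t_on, t_off, b}`` or
    ``None`` on optimizer failure; ``gof`` is the coefficient of
    determination R^2 of the fit on the segment.
    """
    seg = np.asarray(segment, dtype=float)
    t = np.asarray(times, dtype=float)
    if seg.size != t.size or seg.size < 5:
        raise ValueError("segment and times must align and have >= 5 samples")

    a0 = max(float(seg.max()) - baseline, 1e-6)
    lo = [t[0] - 1.0, 1e-9, 1e-3, profile.t_off_floor, -np.inf]
    hi = [t[-1], np.inf, 2.0, 20.0, np.inf]
    p0 = [
        float(np.clip(t0_init, lo[0], hi[0])),
        a0,
        0.1,
        profile.t_off_floor,
        baseline,
    ]
    try:
        popt, _ = curve_fit(
            _model, t, seg, p0=p0, bounds=(lo, hi), maxfev=2000, method="trf"
        )
    except (RuntimeError, ValueError):
        return None, 0.0
    resid = seg - _model(t, *popt)
    ss_tot = float(np.sum((seg - seg.mean()) ** 2))
    if ss_tot == 0.0:
        return None, 0.0
    gof = 1.0 - float(np.sum(resid**2)) / ss_tot
    params = {
        "t0": popt[0], "A": popt[1], "t_on": popt[2], "t_off": popt[3],
        "b": popt[4],
    }
    return params, gof


def _upward_crossings(work: np.ndarray, threshold: float) -> np.ndarray:
    above = work > threshold
    cross = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        cross = np.concatenate(([0], cross))
    return cross


def _truncate_at_next_rise(
    seg: np.ndarray, cross_rel: int, rise_height: float
) -> int | None:
    """Index (relative to seg) of the valley between the first and second
    prominent peaks after the crossing — evidence of a following transient
    inside the window; the fit window is truncated there.  None if the
    window holds a single peak."""
    tail = seg[cross_rel:]
    if tail.size < 8:
        return None
    # 3-frame boxcar suppresses single-sample noise peaks while keeping
    # transients a few frames apart resolvable
    pad = np.pad(tail, 1, mode="edge")
    smooth = np.convolve(pad, np.ones(3) / 3.0, mode="valid")
    peaks, _ = signal.find_peaks(smooth, prominence=max(rise_height, 1e-12))
    if peaks.size < 2:
        return None
    valley = int(np.argmin(tail[peaks[0] : peaks[1] + 1])) + peaks[0]
    return cross_rel + valley


def detect_events(
    trace: np.ndarray,
    profile: SensorProfile,
    fps: float,
    cell_id: int = 0,
    gof_min: float = GOF_MIN,
    max_passes: int = 50,
) -> list[CalciumEvent]:
    """Iterative detect-fit-subtract scan of a single trace.

    The threshold is computed once from the original trace; accepted fits
    are subtracted from a working copy and the trace is re-scanned until a
    full pass accepts nothing new.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    if trace.size < 4:
        return []

    med = float(np.median(trace))
    mad = float(np.median(np.abs(trace - med)))
    with warnings.catch_warnings():
        if mad == 0.0 and not np.any(trace != med):
            return []  # constant trace: nothing to detect
        warnings.simplefilter("ignore", RuntimeWarning)
        threshold = mad_threshold(trace, profile.mad_multiplier)

    pre = int(round(0.5 * fps))  # 0.5 s before the crossing
    post = int(round(4.0 * profile.t_off_floor * fps))
    rise_height = max(0.5 * (threshold - med), 3.0 * mad)

    work = trace.copy()
    times = np.arange(trace.size) / fps
    events: list[CalciumEvent] = []

    for _ in range(max_passes):
        accepted_this_pass = False
        crossings = _upward_crossings(work, threshold)
        taken = np.array([e.t0 for e in events])
        for c in crossings:
            if taken.size and np.any(np.abs(taken - times[c]) < 2.0 / fps):
                continue  # too close to an already-fitted onset
            lo = max(0, c - pre)
            hi = min(trace.size, c + post + 1)
            seg = work[lo:hi]
            if seg.size < 5:
                continue
            cut = _truncate_at_next_rise(seg, c - lo, rise_height)
            if cut is not None and cut + 1 >= 5:
                seg = seg[: cut + 1]
                hi = lo + cut + 1
            params, gof = fit_event(
                seg, times[lo:hi], t0_init=times[c] - 1.0 / fps,
                profile=profile, baseline=med,
            )
            if params is None or not is_acceptable_fit(gof, gof_min):
                continue
            ev = CalciumEvent(
                cell_id=cell_id,
                t0=float(params["t0"]),
                A=float(params["A"]),
                t_on=float(params["t_on"]),
                t_off=float(params["t_off"]),
                gof=float(gof),
            )
            events.append(ev)
            taken = np.append(taken, ev.t0)
            work -= ev.A * transient_kernel(times - ev.t0, ev.t_on, ev.t_off)
            accepted_this_pass = True
        if not accepted_this_pass:
            break

    events.sort(key=lambda e: e.t0)
    return events


def detect_events_matrix(
    traces: TraceMatrix, profile: SensorProfile, gof_min: float = GOF_MIN
) -> list[CalciumEvent]:
    """Run :func:`detect_events` on every row of a trace matrix."""
    out: list[CalciumEvent] = []
    for i in range(traces.n_cells):
        out.extend(
            detect_events(
                traces.values[i], profile, traces.fps,
                cell_id=int(traces.cell_ids[i]), gof_min=gof_min,
            )
        )
    return out
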