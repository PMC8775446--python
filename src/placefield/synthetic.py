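"""Synthetic sessions: trajectory, ground-truth place cells, spikes, traces.

Emulates a mouse freely exploring an elevated O-shaped circular track
(50 cm outer diameter, 5 cm lane width) for 15 minutes at 20 fps,
reversing direction at random, with place cells whose firing becomes
spatially selective only after a configurable onset time.  Every
parameter is known, so downstream stages (event detection, place-field
detection, tuning latency, manifold embedding) are testable by recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import i0e

from .events import CalciumEvent, TraceMatrix, kernel_peak_gain, transient_kernel

__all__ = [
    "TrackGeometry",
    "Trajectory",
    "GroundTruthCell",
    "SpikeTrain",
    "KernelParams",
    "simulate_trajectory",
    "sample_spikes",
    "render_traces",
    "spikes_to_events",
    "tile_place_cells",
    "SyntheticSession",
    "make_session",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class TrackGeometry:
    """O-shaped circular track divided into sectorial bins."""

    outer_diameter: float = 50.0  # cm
    width: float = 5.0  # cm (lane width)
    n_bins: int = 20

    def __post_init__(self) -> None:
        if not (self.outer_diameter > 2 * self.width > 0):
            raise ValueError("require outer_diameter > 2*width > 0")
        if self.n_bins < 4:
            raise ValueError("n_bins must be >= 4")

    @property
    def centerline_radius(self) -> float:
        return (self.outer_diameter - self.width) / 2.0

    @property
    def circumference(self) -> float:
        return TWO_PI * self.centerline_radius

    @property
    def bin_width(self) -> float:
        """Angular bin width in radians."""
        return TWO_PI / self.n_bins

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def bin_of(self, theta: np.ndarray) -> np.ndarray:
        """Bin index for angular position(s); bin i covers [i*w, (i+1)*w)."""
        idx = np.floor(np.mod(theta, TWO_PI) / self.bin_width).astype(int)
        return np.minimum(idx, self.n_bins - 1)


@dataclass
class Trajectory:
    """Per-frame position on the track (times, cartesian, angle, speed)."""

    t: np.ndarray  # seconds, constant step 1/fps
    x: np.ndarray  # cm
    y: np.ndarray  # cm
    theta: np.ndarray  # radians in [0, 2pi)
    speed: np.ndarray  # cm/s (tangential, signed magnitude removed)
    fps: float

    @property
    def duration(self) -> float:
        return self.t.size / self.fps

    @property
    def theta_unwrapped(self) -> np.ndarray:
        return np.unwrap(self.theta)

    def theta_at(self, times: np.ndarray) -> np.ndarray:
        """Angular position interpolated (on the unwrapped angle) at arbitrary times."""
        unwrapped = np.interp(times, self.t, self.theta_unwrapped)
        return np.mod(unwrapped, TWO_PI)


@dataclass(frozen=True)
class GroundTruthCell:
    """Known tuning of one simulated neuron.

    Before ``onset_time`` a place cell fires homogeneously at the spatial
    average of its tuned rate; afterwards the rate is a von Mises bump.
    Non-place cells (``is_place_cell=False``) always fire homogeneously.
    """

    cell_id: int
    is_place_cell: bool
    field_center: float  # radians
    tuning_width: float  # radians (von Mises sigma; kappa = 1/sigma^2)
    in_field_rate: float  # events/s at bump peak
    out_field_rate: float  # events/s far from the field
    onset_time: float = 0.0  # seconds

    def __post_init__(self) -> None:
        if self.is_place_cell:
            if not (self.in_field_rate > self.out_field_rate >= 0):
                raise ValueError("require in_field_rate > out_field_rate >= 0")
            if self.tuning_width <= 0:
                raise ValueError("tuning_width must be positive")

    def rate_at(self, theta: np.ndarray) -> np.ndarray:
        """Tuned event rate (events/s) at angular position(s)."""
        kappa = 1.0 / self.tuning_width**2
        bump = np.exp(kappa * (np.cos(theta - self.field_center) - 1.0))
        return self.out_field_rate + (self.in_field_rate - self.out_field_rate) * bump

    @property
    def mean_rate(self) -> float:
        """Spatial average of the tuned rate over a uniformly covered track."""
        kappa = 1.0 / self.tuning_width**2
        # mean of exp(kappa*(cos - 1)) over the circle = e^-kappa I0(kappa) = i0e
        return float(
            self.out_field_rate
            + (self.in_field_rate - self.out_field_rate) * i0e(kappa)
        )


@dataclass
class SpikeTrain:
    cell_id: int
    spike_times: np.ndarray  # seconds, sorted ascending


@dataclass(frozen=True)
class KernelParams:
    """Calcium transient kinetics and trace noise."""

    t_on: float = 0.1  # s, rise time constant
    t_off: float = 0.6  # s, decay time constant
    amplitude_mean: float = 1.0
    amplitude_cv: float = 0.3
    noise_sigma: float = 0.0  # additive white noise sd, trace units

    def __post_init__(self) -> None:
        if self.t_on <= 0:
            raise ValueError("t_on must be positive")
        if self.t_off < self.t_on:
            raise ValueError("t_off must be >= t_on")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def peak_amplitude(self) -> float:
        """Realised mean peak height of a transient (A * kernel gain)."""
        return self.amplitude_mean * kernel_peak_gain(self.t_on, self.t_off)

    def with_snr(self, snr: float) -> "KernelParams":
        """Copy with noise_sigma set so that peak / noise_sd == snr."""
        return replace(self, noise_sigma=self.peak_amplitude / snr)


def simulate_trajectory(
    geometry: TrackGeometry,
    duration: float,
    fps: float,
    mean_speed: float = 3.0,
    turn_prob: float = 0.1,
    seed: int | None = 0,
    radial_jitter_sd: float = 0.8,
) -> Trajectory:
    """Run-and-reverse random walk along the track centerline.

    The animal moves at ``mean_speed`` along the circular centerline and
    reverses direction as a Bernoulli event with probability ``turn_prob``
    per second (applied per frame as turn_prob/fps).  Radial position
    jitters inside the lane as a smoothed Gaussian walk clipped to the
    annulus, emulating that the mouse does not follow the centerline
    exactly; only the angular coordinate is analysed downstream.
    """
    if duration <= 0 or fps <= 0:
        raise ValueError("duration and fps must be positive")
    if not (0.0 <= turn_prob <= 1.0):
        raise ValueError("turn_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fps))
    dt = 1.0 / fps
    omega = mean_speed / geometry.centerline_radius  # rad/s

    reversals = rng.random(n) < turn_prob * dt
    direction = np.where(np.mod(np.cumsum(reversals), 2) == 0, 1.0, -1.0)
    dtheta = direction * omega * dt
    theta = np.mod(np.concatenate(([0.0], np.cumsum(dtheta[:-1]))), TWO_PI)

    # radial jitter: AR(1) walk, clipped inside the lane
    half = geometry.width / 2.0 - 0.25
    r_dev = np.empty(n)
    r_dev[0] = 0.0
    eps = rng.normal(0.0, radial_jitter_sd * np.sqrt(dt), n)
    rho = np.exp(-dt / 1.0)  # 1 s relaxation
    for i in range(1, n):
        r_dev[i] = rho * r_dev[i - 1] + eps[i]
    r = geometry.centerline_radius + np.clip(r_dev, -half, half)

    t = np.arange(n) * dt
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    speed = np.full(n, mean_speed)
    return Trajectory(t=t, x=x, y=y, theta=theta, speed=speed, fps=fps)


def sample_spikes(
    traj: Trajectory,
    cells: list[GroundTruthCell],
    seed: int | None = 0,
) -> list[SpikeTrain]:
    """Inhomogeneous Poisson event times driven by the trajectory.

    Per frame of duration 1/fps the count is Poisson(rate * dt) and each
    event is placed uniformly within the frame.
    """
    if not cells:
        raise ValueError("cells must be non-empty")
    rng = np.random.default_rng(seed)
    dt = 1.0 / traj.fps
    out: list[SpikeTrain] = []
    for cell in cells:
        if cell.is_place_cell:
            rate = cell.rate_at(traj.theta)
            if cell.onset_time > 0:
                rate = np.where(traj.t < cell.onset_time, cell.mean_rate, rate)
        else:
            rate = np.full(traj.t.size, cell.out_field_rate)
        counts = rng.poisson(rate * dt)
        frames = np.repeat(np.arange(traj.t.size), counts)
        times = traj.t[frames] + rng.random(frames.size) * dt
        times.sort()
        out.append(SpikeTrain(cell_id=cell.cell_id, spike_times=times))
    return out


def render_traces(
    spikes: list[SpikeTrain],
    kernel: KernelParams,
    fps: float,
    duration: float,
    seed: int | None = 0,
) -> TraceMatrix:
    """Render spike trains into noisy fluorescence traces.

    Each spike adds ``A * (1 - e^(-dt/t_on)) e^(-dt/t_off)``; amplitudes
    are log-normal with the stated mean and CV; transients sum linearly on
    a zero baseline; i.i.d. Gaussian noise of sd ``noise_sigma`` is added.
    """
    if duration <= 0 or fps <= 0:
        raise ValueError("duration and fps must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fps))
    times = np.arange(n) / fps

    if kernel.amplitude_cv > 0:
        sig2 = np.log(1.0 + kernel.amplitude_cv**2)
        mu = np.log(kernel.amplitude_mean) - sig2 / 2.0
    # kernel support: decays below 1e-8 well within 20 decay constants
    support = int(np.ceil((kernel.t_on + 20.0 * kernel.t_off) * fps)) + 1

    values = np.zeros((len(spikes), n))
    for row, train in enumerate(spikes):
        st = np.asarray(train.spike_times, dtype=float)
        if st.size and (st.max() >= duration or st.min() < 0):
            raise ValueError("spike time outside [0, duration)")
        if kernel.amplitude_cv > 0:
            amps = rng.lognormal(mu, np.sqrt(sig2), st.size)
        else:
            amps = np.full(st.size, kernel.amplitude_mean)
        tr = values[row]
        for t0, a in zip(st, amps):
            i0 = int(np.ceil(t0 * fps))
            i1 = min(n, i0 + support)
            if i0 >= n:
                continue
            tr[i0:i1] += a * transient_kernel(times[i0:i1] - t0, kernel.t_on, kernel.t_off)
    if kernel.noise_sigma > 0:
        values += rng.normal(0.0, kernel.noise_sigma, values.shape)
    return TraceMatrix(
        values=values, fps=fps, cell_ids=np.array([s.cell_id for s in spikes])
    )


def spikes_to_events(spikes: list[SpikeTrain], kernel: KernelParams | None = None) -> list[CalciumEvent]:
    """Ground-truth spike times as ideal calcium events (for stage isolation)."""
    k = kernel or KernelParams()
    out = []
    for train in spikes:
        for t0 in train.spike_times:
            out.append(
                CalciumEvent(
                    cell_id=train.cell_id, t0=float(t0), A=k.amplitude_mean,
                    t_on=k.t_on, t_off=k.t_off, gof=1.0,
                )
            )
    return out


def tile_place_cells(
    n_cells: int,
    in_field_rate: float = 1.0,
    out_field_rate: float = 0.05,
    tuning_width: float = 0.35,
    onset_time: float = 0.0,
    seed: int | None = None,
    rate_jitter_cv: float = 0.0,
) -> list[GroundTruthCell]:
    """Place cells with field centers tiling the track uniformly."""
    rng = np.random.default_rng(seed)
    centers = (np.arange(n_cells) + 0.5) * TWO_PI / n_cells
    cells = []
    for i, c in enumerate(centers):
        rate = in_field_rate
        if rate_jitter_cv > 0:
            rate = float(in_field_rate * rng.lognormal(0.0, rate_jitter_cv))
        cells.append(
            GroundTruthCell(
                cell_id=i, is_place_cell=True, field_center=float(c),
                tuning_width=tuning_width, in_field_rate=rate,
                out_field_rate=out_field_rate, onset_time=onset_time,
            )
        )
    return cells


@dataclass
class SyntheticSession:
    """A fully specified simulated session (ground truth retained)."""

    geometry: TrackGeometry
    trajectory: Trajectory
    cells: list[GroundTruthCell]
    spikes: list[SpikeTrain]
    traces: TraceMatrix
    kernel: KernelParams

    @property
    def true_events(self) -> list[CalciumEvent]:
        return spikes_to_events(self.spikes, self.kernel)


def make_session(
    cells: list[GroundTruthCell],
    geometry: TrackGeometry | None = None,
    duration: float = 900.0,
    fps: float = 20.0,
    mean_speed: float = 3.0,
    turn_prob: float = 0.1,
    kernel: KernelParams | None = None,
    snr: float | None = None,
    seed: int = 0,
) -> SyntheticSession:
    """Simulate trajectory, spikes and traces for a set of ground-truth cells.

    Defaults emulate the study conditions: a 15-min session at 20 fps on a
    50 cm / 5 cm O-shaped track, with a mean speed giving roughly 19 laps
    (a lap takes ~47 s at 3 cm/s on the 22.5 cm-radius centerline).
    """
    geometry = geometry or TrackGeometry()
    kernel = kernel or KernelParams()
    if snr is not None:
        kernel = kernel.with_snr(snr)
    traj = simulate_trajectory(
        geometry, duration, fps, mean_speed=mean_speed, turn_prob=turn_prob,
        seed=seed,
    )
    spikes = sample_spikes(traj, cells, seed=seed + 1)
    traces = render_traces(spikes, kernel, fps, duration, seed=seed + 2)
    return SyntheticSession(
        geometry=geometry, trajectory=traj, cells=cells, spikes=spikes,
        traces=traces, kernel=kernel,
    )
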