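"""Place-field detection, selectivity scoring, and tuning latency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import placefield as plf
from placefield.events import CalciumEvent
from placefield.fields import (
    AttendanceEpoch,
    SpatialEventMap,
    attendances,
    bin_events,
    classify_and_latency,
    detect_fields,
    gaussian_smooth,
    selectivity_score,
    smooth_normalize,
)


def ev(t0, cell=0):
    return CalciumEvent(cell_id=cell, t0=t0, A=1.0, t_on=0.1, t_off=0.6, gof=1.0)


def const_traj(geometry, thetas, fps=20.0):
    thetas = np.asarray(thetas, dtype=float)
    r = geometry.centerline_radius
    return plf.Trajectory(
        t=np.arange(thetas.size) / fps, x=r * np.cos(thetas),
        y=r * np.sin(thetas), theta=np.mod(thetas, 2 * np.pi),
        speed=np.zeros(thetas.size), fps=fps,
    )


def lap_traj(geometry, n_laps=5, frames_per_lap=400, fps=20.0):
    th = np.linspace(0, n_laps * 2 * np.pi, n_laps * frames_per_lap,
                     endpoint=False)
    return const_traj(geometry, th, fps)


class TestBinning:
    def test_all_events_at_theta_zero(self, geometry):
        traj = const_traj(geometry, np.zeros(100))
        m = bin_events([ev(0.5), ev(1.0), ev(2.0)], traj, geometry)
        assert m.bin_counts[0] == 3 and m.bin_counts.sum() == 3

    def test_one_event_per_bin_center(self, geometry):
        th = geometry.bin_centers()
        traj = const_traj(geometry, np.repeat(th, 20))
        events = [ev((20 * i + 10) / 20.0) for i in range(20)]
        m = bin_events(events, traj, geometry)
        assert np.array_equal(m.bin_counts, np.ones(20, dtype=int))

    def test_boundary_event_goes_to_right_bin(self, geometry):
        """Bin intervals are half-open [start, end): an event exactly on the
        boundary belongs to the upper bin."""
        traj = const_traj(geometry, np.full(100, geometry.bin_width))
        m = bin_events([ev(1.0)], traj, geometry)
        assert m.bin_counts[1] == 1

    def test_event_outside_time_range_rejected(self, geometry):
        traj = const_traj(geometry, np.zeros(100))
        with pytest.raises(ValueError):
            bin_events([ev(50.0)], traj, geometry)


class TestSmoothing:
    def test_delta_gives_symmetric_wrapped_bump(self, geometry):
        counts = np.zeros(20, dtype=int)
        counts[3] = 7
        m = smooth_normalize(SpatialEventMap(0, counts))
        assert m.smoothed[3] == 1.0
        for j in range(1, 10):
            assert m.smoothed[(3 - j) % 20] == pytest.approx(
                m.smoothed[(3 + j) % 20], abs=1e-12)

    def test_uniform_counts_stay_uniform(self):
        m = smooth_normalize(SpatialEventMap(0, np.full(20, 4)))
        assert np.allclose(m.smoothed, 1.0)

    def test_two_antipodal_deltas_identical_bumps(self):
        counts = np.zeros(20, dtype=int)
        counts[2] = counts[12] = 5
        m = smooth_normalize(SpatialEventMap(0, counts))
        assert np.allclose(np.roll(m.smoothed, 10), m.smoothed, atol=1e-12)

    def test_score_smoothing_matches_bruteforce(self):
        """In-package Gaussian smoothing vs an explicit loop re-implementation
        (reflect padding, 4-sigma truncation) on an 8-vector."""
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1.0])
        sigma = 1.0
        r = int(4 * sigma + 0.5)
        kern = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
        kern = kern / kern.sum()
        expected = np.empty_like(x)
        for i in range(x.size):
            acc = 0.0
            for j in range(-r, r + 1):
                idx = i + j
                while idx < 0 or idx >= x.size:  # symmetric reflection
                    idx = -idx - 1 if idx < 0 else 2 * x.size - idx - 1
                acc += kern[j + r] * x[idx]
            expected[i] = acc
        got = gaussian_smooth(x, sigma, mode="reflect")
        assert np.max(np.abs(got - expected)) < 1e-12


class TestDetectFields:
    def make_map(self, smoothed):
        m = SpatialEventMap(0, np.ones(len(smoothed), dtype=int))
        m.smoothed = np.asarray(smoothed, dtype=float)
        return m

    def test_three_bin_bump_yields_width_five(self, geometry):
        sm = np.full(20, 0.1)
        sm[5:8] = [0.8, 1.0, 0.8]
        (f,) = detect_fields(self.make_map(sm), geometry)
        assert f.width_bins == 5
        assert set(f.bins) == {4, 5, 6, 7, 8}
        assert f.center_bin == pytest.approx(6.0, abs=1e-6)

    def test_wide_field_excluded(self, geometry):
        sm = np.full(20, 0.1)
        sm[2:11] = 0.9  # run of 9 -> expanded 11 > 10
        assert detect_fields(self.make_map(sm), geometry) == []

    def test_two_separated_bumps_two_fields(self, geometry):
        sm = np.full(20, 0.1)
        sm[2:4] = 0.9
        sm[12:14] = 1.0
        fields = detect_fields(self.make_map(sm), geometry)
        assert len(fields) == 2

    def test_all_above_threshold_no_field(self, geometry):
        assert detect_fields(self.make_map(np.ones(20)), geometry) == []

    def test_wraparound_run_detected(self, geometry):
        sm = np.full(20, 0.1)
        sm[19] = 0.9
        sm[0] = 1.0
        (f,) = detect_fields(self.make_map(sm), geometry)
        assert set(f.bins) == {18, 19, 0, 1}

    def test_rotation_equivariance(self, geometry, small_session):
        """Rotating events and trajectory by one bin rotates each center by
        exactly one bin."""
        sess = small_session
        events = [e for e in sess.true_events if e.cell_id == 3]
        traj = sess.trajectory
        m1 = smooth_normalize(bin_events(events, traj, geometry))
        rot = plf.Trajectory(
            t=traj.t, x=traj.x.copy(), y=traj.y.copy(),
            theta=np.mod(traj.theta + geometry.bin_width, 2 * np.pi),
            speed=traj.speed, fps=traj.fps,
        )
        m2 = smooth_normalize(bin_events(events, rot, geometry))
        f1 = detect_fields(m1, geometry)
        f2 = detect_fields(m2, geometry)
        assert len(f1) == len(f2) >= 1
        for a, b in zip(f1, f2):
            assert plf.signed_circular_diff(b.center_bin, a.center_bin, 20) \
                == pytest.approx(1.0, abs=1e-6)


class TestAttendances:
    def test_never_entering_field_empty(self, geometry):
        traj = const_traj(geometry, np.zeros(200))
        field = plf.PlaceField(0, 10.0, (9, 10, 11), 3, 20)
        assert attendances(traj, field, geometry) == []

    def test_one_epoch_per_lap(self, geometry):
        traj = lap_traj(geometry, n_laps=5)
        field = plf.PlaceField(0, 10.0, (9, 10, 11), 3, 20)
        eps = attendances(traj, field, geometry)
        assert len(eps) == 5
        assert [e.index for e in eps] == [1, 2, 3, 4, 5]
        assert all(e.t_enter < e.t_exit for e in eps)

    def test_sitting_inside_field_single_epoch(self, geometry):
        traj = const_traj(geometry, np.full(400, 10.5 * geometry.bin_width))
        field = plf.PlaceField(0, 10.0, (9, 10, 11), 3, 20)
        (epoch,) = attendances(traj, field, geometry)
        assert epoch.t_enter == traj.t[0]
        assert epoch.t_exit == pytest.approx(traj.t[-1] + 1 / traj.fps)

    def test_debounce_merges_brief_excursions(self, geometry):
        th = np.concatenate([
            np.full(100, 10 * geometry.bin_width),  # 5 s in field
            np.full(10, 0.0),                       # 0.5 s out (< debounce)
            np.full(100, 10 * geometry.bin_width),
        ])
        traj = const_traj(geometry, th)
        field = plf.PlaceField(0, 10.0, (9, 10, 11), 3, 20)
        assert len(attendances(traj, field, geometry)) == 1
        assert len(attendances(traj, field, geometry, debounce=0.1)) == 2


class TestSelectivity:
    EPOCH = AttendanceEpoch(1, 10.0, 12.0, (5.0, 10.0), (12.0, 18.0))

    def test_all_events_in_field_scores_one(self):
        assert selectivity_score(np.array([10.5, 11.0, 11.9]), self.EPOCH) == 1.0

    def test_half_in_half_out(self):
        assert selectivity_score(np.array([10.5, 11.0, 6.0, 13.0]),
                                 self.EPOCH) == 0.5

    def test_no_in_field_events_scores_zero(self):
        assert selectivity_score(np.array([6.0, 14.0]), self.EPOCH) == 0.0

    def test_silent_lap_is_scoreless(self):
        assert np.isnan(selectivity_score(np.array([100.0]), self.EPOCH))


class TestClassifyLatency:
    def make_epochs(self, n, spacing=10.0):
        return [AttendanceEpoch(i + 1, i * spacing, i * spacing + 2,
                                ((i - 1) * spacing + 2, i * spacing),
                                (i * spacing + 2, (i + 1) * spacing))
                for i in range(n)]

    def field(self):
        return plf.PlaceField(0, 10.0, (9, 10, 11), 3, 20)

    def test_immediately_selective_field(self):
        rec = classify_and_latency(self.field(), self.make_epochs(3),
                                   np.array([1.0, 1.0, 1.0]))
        assert rec.is_place_cell and rec.n_spec == 0 and rec.t_spec == 0.0

    def test_all_zero_scores_not_a_place_cell(self):
        rec = classify_and_latency(self.field(), self.make_epochs(5),
                                   np.zeros(5))
        assert not rec.is_place_cell and rec.n_spec is None

    def test_delayed_tuning_matches_bruteforce_oracle(self):
        """Smoothing + run finding on [0,0,0,0,1,1,1,1] against an
        independent loop implementation."""
        raw = np.array([0, 0, 0, 0, 1, 1, 1, 1.0])
        rec = classify_and_latency(self.field(), self.make_epochs(8), raw)
        # oracle: explicit reflect-padded convolution, then first >=3 run
        sigma, r = 1.0, 4
        kern = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
        kern /= kern.sum()
        sm = np.empty(8)
        for i in range(8):
            acc = 0.0
            for j in range(-r, r + 1):
                idx = i + j
                while idx < 0 or idx >= 8:
                    idx = -idx - 1 if idx < 0 else 16 - idx - 1
                acc += kern[j + r] * raw[idx]
            sm[i] = acc
        rel = sm > 0.5
        run_start = next(i for i in range(6) if rel[i] and rel[i+1] and rel[i+2])
        assert np.max(np.abs(rec.smoothed_scores - sm)) < 1e-12
        assert rec.is_place_cell
        assert rec.n_spec == run_start

    def test_scoreless_epochs_excluded_but_counted(self):
        raw = np.array([np.nan, 1.0, 1.0, 1.0])
        rec = classify_and_latency(self.field(), self.make_epochs(4), raw)
        assert rec.is_place_cell
        assert rec.n_spec == 1  # run starts at visit 2
        assert rec.t_spec == 10.0

    @given(st.lists(st.floats(0, 1), min_size=3, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_monotone_rule(self, scores):
        """Raising any raw score never decreases the relevant-epoch count."""
        raw = np.array(scores)
        epochs = self.make_epochs(raw.size)
        base = classify_and_latency(self.field(), epochs, raw)
        bumped = raw.copy()
        bumped[len(bumped) // 2] = 1.0
        more = classify_and_latency(self.field(), epochs, bumped)
        assert more.relevant.sum() >= base.relevant.sum()


class TestRecovery:
    def test_field_centers_recovered(self, geometry, small_session):
        sess = small_session
        by_cell = {}
        for e in sess.true_events:
            by_cell.setdefault(e.cell_id, []).append(e)
        hits = 0
        for c in sess.cells:
            recs = [r for r in plf.analyze_cell(by_cell.get(c.cell_id, []),
                                                sess.trajectory, geometry)
                    if r.is_place_cell]
            if not recs:
                continue
            true_bin = c.field_center / (2 * np.pi) * 20
            d = min(abs(plf.signed_circular_diff(r.field.center_bin, true_bin,
                                                 20)) for r in recs)
            hits += d <= 1.0
        assert hits >= 0.9 * len(sess.cells)
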