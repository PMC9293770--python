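"""Stitching, change-point parsing, and run classification."""

import numpy as np
import pytest

from phagotrack import (
    AnalysisConfig,
    MotionSegment,
    RunCriteria,
    RunSegment,
    Trajectory,
    classify_runs,
    detect_changepoints,
    parse_constant_velocity,
    stitch_directed,
)
from phagotrack.runs import PAUSE, RUN, SUBTHRESHOLD, StitchedTrack
from phagotrack.trajectory import DIFFUSIVE, DIRECTED

DT = 0.05


def make_traj(n):
    return Trajectory(frames=np.arange(n), times=np.arange(n) * DT,
                      x=np.arange(n, dtype=float), y=np.zeros(n))


def seg(a, b, state=DIRECTED):
    return MotionSegment(a, b, state, 1.8 if state == DIRECTED else 1.0)


class TestStitchDirected:
    def test_short_gap_is_bridged(self):
        traj = make_traj(100)
        segs = [seg(0, 30), seg(31, 33, DIFFUSIVE), seg(34, 60)]
        tracks = stitch_directed(segs, traj, max_gap_frames=5)
        assert len(tracks) == 1
        assert (tracks[0].start_frame, tracks[0].end_frame) == (0, 60)

    def test_long_gap_splits_tracks(self):
        traj = make_traj(100)
        segs = [seg(0, 30), seg(31, 40, DIFFUSIVE), seg(41, 60)]
        tracks = stitch_directed(segs, traj, max_gap_frames=5)
        assert [(t.start_frame, t.end_frame) for t in tracks] == [(0, 30), (41, 60)]

    def test_frame_bookkeeping_by_direct_count(self):
        traj = make_traj(200)
        segs = [seg(5, 40), seg(41, 44, DIFFUSIVE), seg(45, 90),
                seg(91, 130, DIFFUSIVE), seg(131, 170)]
        tracks = stitch_directed(segs, traj, max_gap_frames=5)
        # stitched frame count = member segment spans + included gaps
        assert len(tracks[0]) == (40 - 5 + 1) + 4 + (90 - 45 + 1)
        assert len(tracks[1]) == 170 - 131 + 1
        assert sum(len(t) for t in tracks) == sum(
            s.n_frames for s in segs if s.state == DIRECTED) + 4

    def test_empty_input_gives_empty_output(self):
        assert stitch_directed([], make_traj(10), 5) == []

    def test_track_end_flag(self):
        traj = make_traj(100)
        tracks = stitch_directed([seg(50, 99)], traj, 5)
        assert tracks[0].ends_at_traj_end
        tracks = stitch_directed([seg(50, 90)], traj, 5)
        assert not tracks[0].ends_at_traj_end


def two_piece_oracle(y):
    """Exhaustive least-squares best single change point."""
    n = len(y)
    t = np.arange(n, dtype=float)
    best, best_c = np.inf, None
    for c in range(2, n - 2):
        r = 0.0
        for sl in (slice(0, c), slice(c, n)):
            coef = np.polyfit(t[sl], y[sl], 1)
            r += np.sum((y[sl] - np.polyval(coef, t[sl])) ** 2)
        if r < best:
            best, best_c = r, c
    return best_c


def make_track(y, start=0, ends_at_end=False):
    n = len(y)
    return StitchedTrack(start_frame=start, end_frame=start + n - 1,
                         times=np.arange(n) * DT, x=np.asarray(y, float),
                         y=np.zeros(n), ends_at_traj_end=ends_at_end)


class TestChangepoints:
    def test_single_constant_velocity_track_no_change_points(self):
        rng = np.random.default_rng(1)
        fp = 0
        for _ in range(50):
            y = 600 * DT * np.arange(150) + rng.normal(0, 9.8, 150)
            fp += len(detect_changepoints(y, min_size=6)) > 0
        assert fp / 50 <= 0.05

    def test_two_piece_track_localized_within_3_frames_of_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            v = np.where(np.arange(120) < 60, 600.0, 100.0) * DT
            y = np.concatenate([[0], np.cumsum(v)[:-1]])
            y = y + rng.normal(0, 9.8, 120)
            cps = detect_changepoints(y, min_size=6)
            assert len(cps) == 1
            assert abs(cps[0] - two_piece_oracle(y)) <= 3
            assert abs(cps[0] - 60) <= 3

    def test_speed_recovered_within_5_percent(self):
        rng = np.random.default_rng(3)
        y = 500 * DT * np.arange(200) + rng.normal(0, 9.8, 200)
        track = make_track(y)
        pieces = parse_constant_velocity(track)
        assert len(pieces) == 1
        assert pieces[0].speed == pytest.approx(500.0, rel=0.05)

    def test_rotation_invariance_of_parse(self):
        rng = np.random.default_rng(4)
        v = np.where(np.arange(160) < 80, 700.0, 150.0) * DT
        x = np.concatenate([[0], np.cumsum(v)[:-1]]) + rng.normal(0, 9.8, 160)
        y = rng.normal(0, 9.8, 160)
        base = StitchedTrack(0, 159, np.arange(160) * DT, x, y, False)
        ref = parse_constant_velocity(base)
        th = 0.83
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xr, yr = R @ np.vstack([x, y])
        rot = StitchedTrack(0, 159, np.arange(160) * DT, xr, yr, False)
        out = parse_constant_velocity(rot)
        assert [p.start_frame for p in out] == [p.start_frame for p in ref]
        for a, b in zip(out, ref):
            assert a.speed == pytest.approx(b.speed, rel=1e-6)

    def test_every_frame_in_exactly_one_piece(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([np.full(70, 600.0), np.full(30, 20.0),
                            np.full(70, -500.0)]) * DT
        y = np.concatenate([[0], np.cumsum(v)[:-1]]) + rng.normal(0, 9.8, 170)
        track = make_track(y, start=100)
        pieces = parse_constant_velocity(track)
        covered = np.zeros(170, dtype=int)
        for p in pieces:
            covered[p.start_frame - 100:p.end_frame - 100 + 1] += 1
        # bounds are inclusive and adjacent pieces share no frame
        assert np.all(covered == 1)

    def test_too_short_track_returns_empty(self):
        track = make_track(np.arange(8, dtype=float))
        assert parse_constant_velocity(track) == []


class TestClassifyRuns:
    def _seg(self, net, speed, dur, censored=False):
        return RunSegment(0, int(dur / DT), dur, net, speed,
                          censored=censored)

    def test_hand_classified_fixture_table(self):
        # hand-computed oracle table: (net nm, speed nm/s, duration s)
        table = [
            (300.0, 600.0, 0.50, RUN),           # passes all three
            (30.0, 40.0, 0.75, PAUSE),           # slow
            (250.0, 55.0, 4.55, RUN),            # slow-ish but qualifying
            (150.0, 600.0, 0.25, SUBTHRESHOLD),  # too little displacement
            (300.0, 1500.0, 0.20, SUBTHRESHOLD), # fast but too brief
            (20.0, 45.0, 0.44, PAUSE),           # slow and tiny
        ]
        segs = [self._seg(n, s, d) for n, s, d, _ in table]
        out = classify_runs(segs, RunCriteria())
        assert [r.kind for r in out] == [k for *_, k in table]
        kinds = [r.kind for r in out]
        assert (kinds.count(RUN), kinds.count(PAUSE),
                kinds.count(SUBTHRESHOLD)) == (2, 2, 2)

    def test_boundary_speed_is_not_a_pause(self):
        out = classify_runs([self._seg(300.0, 50.0, 6.0)], RunCriteria())
        assert out[0].kind == SUBTHRESHOLD

    def test_parsed_slow_piece_is_pause(self):
        rng = np.random.default_rng(6)
        y = 30.0 * DT * np.arange(100) + rng.normal(0, 9.8, 100)
        pieces = classify_runs(parse_constant_velocity(make_track(y)))
        assert all(p.kind == PAUSE for p in pieces)


class TestRecoveryFromSimulatedRuns:
    def test_mean_run_speed_recovered_within_10_percent(self):
        # many independent constant-velocity tracks with known speeds
        rng = np.random.default_rng(7)
        cfg = AnalysisConfig()
        true_speeds, est_speeds = [], []
        while len(est_speeds) < 300:
            v = rng.uniform(200, 900)
            n = rng.integers(30, 120)
            y = v * DT * np.arange(n) + rng.normal(0, 9.8, n)
            for p in classify_runs(parse_constant_velocity(make_track(y), cfg)):
                if p.kind == RUN:
                    true_speeds.append(v)
                    est_speeds.append(p.speed)
        assert np.mean(est_speeds) == pytest.approx(np.mean(true_speeds),
                                                    rel=0.10)
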