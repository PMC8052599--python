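"""Segmentation, speed/accuracy statistics, exclusion filters, standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mousestress.event_io import EventKind, EventLog, ValidationError
from mousestress.features import (
    DegenerateFeatureError,
    ExclusionReport,
    FilterConfig,
    Trajectory,
    apply_exclusions,
    frame_to_features,
    features_to_frame,
    read_features,
    recording_features,
    segment_trajectories,
    standardize_features,
    trajectory_accuracy,
    trajectory_speed,
    write_features,
)


def log_from(t, x, y, kinds, subject="s1", recording="r1"):
    return EventLog(subject, recording, np.asarray(t), np.asarray(x), np.asarray(y), np.asarray(kinds, dtype="U5"))


def traj_from_steps(dx, dy, dt_ms=8):
    """Build a trajectory from integer per-step displacements."""
    x = np.concatenate([[0], np.cumsum(dx)])
    y = np.concatenate([[0], np.cumsum(dy)])
    t = dt_ms * np.arange(len(x))
    return Trajectory(t, x, y, EventKind.CLICK)


def movement_log(n_moves, dt_ms=8, terminal="click", t0=0, step=(3, 4)):
    t = t0 + dt_ms * np.arange(n_moves + 1)
    x = step[0] * np.arange(n_moves + 1)
    y = step[1] * np.arange(n_moves + 1)
    kinds = ["move"] * n_moves + [terminal]
    return t, x, y, kinds


class TestSegmentation:
    def test_single_segment_duration(self):
        # moves at t=0..2000 ms then click at 2000 ms -> one 2.0 s trajectory
        t = np.arange(0, 2000, 8)
        n = len(t)
        log = log_from(
            np.append(t, 2000), np.arange(n + 1), np.arange(n + 1), ["move"] * n + ["click"]
        )
        trajs = segment_trajectories(log)
        assert len(trajs) == 1
        assert trajs[0].duration_s == pytest.approx(2.0)
        assert trajs[0].terminal_kind is EventKind.CLICK

    def test_short_run_below_duration_floor_dropped(self):
        t, x, y, k = movement_log(62)  # ~0.5 s of moves
        assert segment_trajectories(log_from(t, x, y, k)) == []

    def test_max_duration_default_vs_sensitivity_setting(self):
        t, x, y, k = movement_log(15 * 125)  # 15 s run
        log = log_from(t, x, y, k)
        assert segment_trajectories(log, FilterConfig()) == []
        wide = FilterConfig(max_duration_s=20.0)
        assert len(segment_trajectories(log, wide)) == 1

    def test_duration_bounds_inclusive(self):
        t, x, y, k = movement_log(125)  # exactly 1.0 s
        assert len(segment_trajectories(log_from(t, x, y, k))) == 1
        t, x, y, k = movement_log(10 * 125)  # exactly 10.0 s
        assert len(segment_trajectories(log_from(t, x, y, k))) == 1

    def test_unvalidated_log_rejected(self):
        log = log_from([0, 16, 8, 24], [0, 1, 2, 3], [0, 0, 0, 0], ["move"] * 3 + ["click"])
        with pytest.raises(ValidationError, match="decreasing"):
            segment_trajectories(log)

    def test_segmentation_is_a_partition(self, rng):
        # random stream: every click/wheel ends at most one trajectory and
        # no move event is claimed twice
        n = 600
        kinds = np.where(rng.random(n) < 0.05, rng.choice(["click", "wheel"], n), "move")
        log = log_from(8 * np.arange(n), rng.integers(0, 500, n), rng.integers(0, 500, n), kinds)
        permissive = FilterConfig(min_duration_s=1e-9, max_duration_s=1e9)
        trajs = segment_trajectories(log, permissive)
        n_terminals_with_moves = 0
        prev = -1
        term_idx = np.flatnonzero(kinds != "move")
        for j in term_idx:
            if j - prev > 1:
                n_terminals_with_moves += 1
            prev = j
        assert len(trajs) == n_terminals_with_moves
        spans = sorted((tr.t[0], tr.t[-1]) for tr in trajs)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 < b0 or (a1 == b0)  # segments never interleave
        assert sum(tr.n_steps for tr in trajs) <= n - 1


class TestSpeed:
    def test_straight_path_hand_computed(self):
        # 100 steps of (3,4) px -> 5 px each, over 1 s -> 500 px/s
        traj = traj_from_steps([3] * 100, [4] * 100, dt_ms=10)
        assert trajectory_speed(traj) == pytest.approx(500.0)

    def test_stationary_pointer_zero_speed(self):
        traj = Trajectory(np.array([0, 1000, 2000]), np.zeros(3, int), np.zeros(3, int), EventKind.CLICK)
        assert trajectory_speed(traj) == 0.0

    def test_path_length_not_net_displacement(self):
        # back and forth +-10 px, net 0, total 200 px over 1 s -> 200 px/s
        dx = [10, -10] * 10
        traj = traj_from_steps(dx, [0] * 20, dt_ms=50)
        assert np.isclose(traj.x[-1], 0)
        assert trajectory_speed(traj) == pytest.approx(200.0)

    def test_translation_invariance_and_scale_equivariance(self, rng):
        dx = rng.integers(-5, 6, 50)
        dy = rng.integers(-5, 6, 50)
        base = traj_from_steps(dx, dy)
        shifted = Trajectory(base.t, base.x + 1000, base.y - 377, EventKind.CLICK)
        assert trajectory_speed(shifted) == pytest.approx(trajectory_speed(base))
        scaled = Trajectory(base.t, 3 * base.x, 3 * base.y, EventKind.CLICK)
        assert trajectory_speed(scaled) == pytest.approx(3 * trajectory_speed(base))

    def test_zero_duration_is_error(self):
        traj = Trajectory(np.array([5, 5]), np.array([0, 1]), np.array([0, 1]), EventKind.CLICK)
        with pytest.raises(ValidationError):
            trajectory_speed(traj)


def accuracy_oracle(dx, dy):
    """Independent brute-force count of unchanged-direction steps."""
    sgn = lambda v: (v > 0) - (v < 0)
    sx = [sgn(d) for d in dx]
    sy = [sgn(d) for d in dy]
    comps = [int(sx[i] == sx[i - 1] and sy[i] == sy[i - 1]) for i in range(1, len(dx))]
    return sum(comps) / len(comps)


class TestAccuracy:
    def test_monotone_path_is_exactly_one(self):
        traj = traj_from_steps([3] * 40, [4] * 40)
        assert trajectory_accuracy(traj) == 1.0

    def test_fully_alternating_is_zero(self):
        traj = traj_from_steps([1, -1] * 20, [0] * 40)
        assert trajectory_accuracy(traj) == 0.0

    def test_hand_counted_mixed_path(self):
        # 9 steps, 8 comparisons, sign changes at comparisons 3, 5 and 6
        dx = [2, 2, 2, -1, -1, 3, -2, -2, -2]
        dy = [1, 1, 1, 1, 1, 1, 1, 1, 1]
        assert accuracy_oracle(dx, dy) == 0.625
        assert trajectory_accuracy(traj_from_steps(dx, dy)) == pytest.approx(0.625)

    def test_pause_counts_as_two_changes(self):
        # stop and resume in the same direction: 0 delta breaks the run twice
        dx = [2, 2, 0, 2, 2]
        dy = [0, 0, 0, 0, 0]
        assert trajectory_accuracy(traj_from_steps(dx, dy)) == pytest.approx(accuracy_oracle(dx, dy))
        assert trajectory_accuracy(traj_from_steps(dx, dy)) == pytest.approx(0.5)

    def test_fewer_than_two_steps_undefined(self):
        traj = traj_from_steps([5], [5])
        assert trajectory_accuracy(traj) is None

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        steps=st.lists(
            st.tuples(st.integers(-4, 4), st.integers(-4, 4)), min_size=2, max_size=60
        )
    )
    def test_matches_brute_force_oracle_and_stays_in_unit_interval(self, steps):
        dx = [s[0] for s in steps]
        dy = [s[1] for s in steps]
        acc = trajectory_accuracy(traj_from_steps(dx, dy))
        assert 0.0 <= acc <= 1.0
        assert acc == pytest.approx(accuracy_oracle(dx, dy))


class TestRecordingFeatures:
    def make_two_traj_log(self):
        # traj 1: 250 steps of (1,0) px / 8 ms -> 125 px/s; traj 2: (3,4)->625 px/s
        t1, x1, y1, k1 = movement_log(250, step=(1, 0))
        t2, x2, y2, k2 = movement_log(250, t0=t1[-1] + 500, step=(3, 4), terminal="wheel")
        return log_from(
            np.concatenate([t1, t2]),
            np.concatenate([x1, x2 + x1[-1]]),
            np.concatenate([y1, y2 + y1[-1]]),
            k1 + k2,
        )

    def test_unweighted_mean_speed_and_terminal_proportions(self):
        feats = recording_features(self.make_two_traj_log())
        assert feats.n_trajectories == 2
        assert feats.speed == pytest.approx((125.0 + 625.0) / 2)
        assert feats.click_prop == 0.5 and feats.wheel_prop == 0.5
        assert feats.click_prop + feats.wheel_prop == 1.0

    def test_all_click_proportion(self):
        t, x, y, k = movement_log(250)
        feats = recording_features(log_from(t, x, y, k))
        assert feats.click_prop == 1.0 and feats.wheel_prop == 0.0

    def test_no_retained_trajectories_signals_empty(self):
        t, x, y, k = movement_log(20)  # 0.16 s, below floor
        assert recording_features(log_from(t, x, y, k)) is None


class TestExclusions:
    def clean_log(self, subject="s1", recording="r1"):
        parts = [movement_log(200, t0=i * 3000, step=(2, 1)) for i in range(12)]
        t = np.concatenate([p[0] for p in parts])
        x = np.concatenate([p[1] for p in parts])
        y = np.concatenate([p[2] for p in parts])
        k = sum((p[3] for p in parts), [])
        return log_from(t, x, y, k, subject=subject, recording=recording)

    def test_constructed_mixed_batch(self):
        empty = log_from([0, 900], [5, 5], [5, 5], ["click", "click"], "sA", "r1")
        nonmono = log_from([0, 16, 8, 2000], [0, 1, 2, 3], [0] * 4, ["move"] * 3 + ["click"], "sB", "r1")
        t, x, y, k = movement_log(200)  # single trajectory -> below the 10 minimum
        sparse = log_from(t, x, y, k, "sC", "r1")
        clean = self.clean_log("sD", "r1")
        feats, report = apply_exclusions([empty, nonmono, sparse, clean])
        assert (
            report.n_no_movement,
            report.n_tracking_error,
            report.n_too_few_trajectories,
        ) == (1, 1, 1)
        assert report.n_retained == len(feats) == 1
        assert feats[0].subject_id == "sD"
        assert report.excluded_subjects == ["sA", "sB", "sC"]

    def test_all_clean_reports_zero_exclusions(self):
        logs = [self.clean_log("s1", f"r{i}") for i in range(3)]
        feats, report = apply_exclusions(logs)
        assert report.n_raw == report.n_retained == 3
        assert report.n_excluded == 0 and report.excluded_subjects == []

    def test_first_hit_counting_keeps_sum_identity(self):
        # a log that is both empty of moves and nonmonotonic counts once,
        # under the first rule
        weird = log_from([10, 0], [0, 0], [0, 0], ["click", "wheel"])
        _, report = apply_exclusions([weird])
        assert report.n_no_movement == 1 and report.n_tracking_error == 0
        assert report.n_retained == 0

    def test_report_sum_identity_on_given_counts(self):
        report = ExclusionReport(2029, 5, 92, 200)
        assert report.n_excluded == 297
        assert report.n_retained == 2029 - 297


class TestStandardize:
    def test_two_point_hand_computation(self):
        df = pd.DataFrame({"speed": [100.0, 300.0], "accuracy": [0.5, 0.7]})
        z, scaler = standardize_features(df)
        assert scaler.sd["speed"] == pytest.approx(141.4213562)
        assert z["speed"].tolist() == pytest.approx([-0.70710678, 0.70710678])
        assert z["speed"].mean() == pytest.approx(0.0) and z["speed"].std(ddof=1) == pytest.approx(1.0)

    def test_constant_column_errors(self):
        df = pd.DataFrame({"speed": [5.0, 5.0, 5.0], "accuracy": [0.1, 0.2, 0.3]})
        with pytest.raises(DegenerateFeatureError):
            standardize_features(df)

    def test_inverse_round_trip(self, rng):
        df = pd.DataFrame({"speed": rng.normal(400, 100, 50), "accuracy": rng.uniform(0.4, 0.9, 50)})
        z, scaler = standardize_features(df)
        back = scaler.inverse(z)
        assert np.allclose(back["speed"], df["speed"]) and np.allclose(back["accuracy"], df["accuracy"])


def test_features_table_round_trip(tmp_path, small_study):
    rows = small_study.features[:25]
    path = tmp_path / "features.csv"
    write_features(rows, path)
    back = read_features(path)
    pd.testing.assert_frame_equal(features_to_frame(back), features_to_frame(rows))
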