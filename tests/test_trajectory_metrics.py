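"""Open-field trajectory reading and locomotion metrics."""

import io

import numpy as np
import pandas as pd
import pytest

import flyseize as fz
from flyseize.arena import AnalysisInterval

from conftest import line_traj, make_traj


def _csv_from_trajs(tmp_path, trajs, drop=None):
    path = tmp_path / "trajs.csv"
    fz.write_trajectories(path, trajs)
    if drop:
        df = pd.read_csv(path)
        df = df.drop(index=drop).reset_index(drop=True)
        df.to_csv(path, index=False)
    return path


class TestLoader:
    def test_two_flies_full_length(self, tmp_path, big_arena):
        trajs = [line_traj(2.0, 600.0), line_traj(1.0, 600.0, angle_rad=1.0)]
        trajs[0].fly_id, trajs[1].fly_id = "a", "b"
        path = _csv_from_trajs(tmp_path, trajs)
        out = fz.load_trajectories(path, arena=big_arena)
        assert len(out) == 2
        assert all(len(t) == 18000 for t in out)

    def test_missing_frame_interpolated_and_flagged(self, tmp_path, big_arena):
        traj = line_traj(2.0, 20.0)
        traj.fly_id = "a"
        path = _csv_from_trajs(tmp_path, [traj], drop=[100])
        (out,) = fz.load_trajectories(path, arena=big_arena)
        assert len(out) == 600
        assert out.gap_mask.sum() == 1 and out.gap_mask[100]
        # linear interpolation restores the constant-velocity point exactly
        assert out.x_mm[100] == pytest.approx(traj.x_mm[100], abs=1e-9)

    def test_non_monotone_time_rejected(self, tmp_path):
        df = pd.DataFrame({
            "frame": [0, 1, 2], "time_s": [0.0, 0.066, 0.033],
            "fly_id": "a", "x_mm": 0.0, "y_mm": 0.0,
        })
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="non-monotone time"):
            fz.load_trajectories(path)

    def test_long_gap_rejects_fly(self, tmp_path, big_arena):
        good = line_traj(2.0, 20.0)
        good.fly_id = "good"
        bad = line_traj(2.0, 20.0)
        bad.fly_id = "bad"
        # remove 40 consecutive frames (> 1 s at 30 fps) from the second fly
        path = _csv_from_trajs(tmp_path, [good, bad],
                               drop=list(range(600 + 100, 600 + 140)))
        out = fz.load_trajectories(path, arena=big_arena, max_gap_s=1.0)
        assert [t.fly_id for t in out] == ["good"]

    def test_out_of_arena_points_clipped(self, tmp_path):
        small = fz.ArenaSpec(diameter_mm=10.0)
        traj = line_traj(5.0, 10.0)  # runs 50 mm, far outside a 10-mm arena
        traj.fly_id = "a"
        path = _csv_from_trajs(tmp_path, [traj])
        with pytest.warns(UserWarning, match="clipped"):
            (out,) = fz.load_trajectories(path, arena=small)
        assert np.all(np.hypot(out.x_mm, out.y_mm) <= 5.0 + 1e-6)


class TestSpeedSeries:
    def test_straight_line_constant_speed(self):
        speed = fz.speed_series(line_traj(5.0, 10.0))
        assert np.allclose(speed, 5.0)

    def test_stationary_fly_zero(self):
        traj = make_traj(np.zeros(300), np.zeros(300))
        assert np.all(fz.speed_series(traj) == 0.0)

    def test_single_frame_jump(self):
        x = np.zeros(300)
        x[150:] = 1.0  # 1 mm step between frames 149 and 150
        traj = make_traj(x, np.zeros(300))
        speed = fz.speed_series(traj, smoothing_frames=1)
        assert speed[149] == pytest.approx(30.0)
        assert np.sum(speed > 0) == 1

    @pytest.mark.parametrize("bad", [0, 2, 4, -1])
    def test_even_or_nonpositive_smoothing_rejected(self, bad):
        with pytest.raises(ValueError):
            fz.speed_series(line_traj(1.0, 10.0), smoothing_frames=bad)


class TestLocomotionSummary:
    IV = AnalysisInterval("obs", 0.0, 120.0)

    def test_straight_line_measures(self, big_arena):
        s = fz.locomotion_summary(line_traj(5.0, 120.0), self.IV, big_arena)
        assert s.average_speed_mm_s == pytest.approx(5.0, rel=1e-9)
        assert s.total_distance_mm == pytest.approx(600.0, rel=1e-3)
        assert s.percent_active_time == 100.0

    def test_stationary_fly_at_center(self, arena):
        traj = make_traj(np.zeros(3600), np.zeros(3600))
        s = fz.locomotion_summary(traj, self.IV, arena)
        assert s.average_speed_mm_s == 0.0
        assert s.percent_time_in_center == 100.0
        assert s.path_linearity is None  # motionless windows are excluded

    def test_half_time_in_center(self, arena):
        # half the frames at the centre, half near the wall (inside arena)
        n = 3600
        x = np.where(np.arange(n) < n // 2, 0.0, 12.0)
        s = fz.locomotion_summary(make_traj(x, np.zeros(n)), self.IV, arena)
        assert s.percent_time_in_center == pytest.approx(50.0)

    def test_empty_interval_errors(self, big_arena):
        iv = AnalysisInterval("later", 500.0, 600.0)
        with pytest.raises(ValueError):
            fz.locomotion_summary(line_traj(5.0, 120.0), iv, big_arena)

    def test_percent_active_monotone_in_threshold(self, arena):
        lab = fz.generate_trajectory(fz.scenario("control_like"), 60.0, arena,
                                     seed=3)
        iv = AnalysisInterval("all", 0.0, 60.0)
        vals = [fz.locomotion_summary(lab.trajectory, iv, arena,
                                      active_speed_threshold=t).percent_active_time
                for t in (0.5, 1.0, 2.0, 5.0)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestPathLinearity:
    IV = AnalysisInterval("obs", 0.0, 20.0)

    def test_straight_path_is_one(self):
        val = fz.path_linearity(line_traj(5.0, 20.0), self.IV)
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_out_and_back_is_zero(self):
        # each 2-s window travels out 1 s then exactly back
        fps, n = 30.0, 600
        seg = np.concatenate([np.arange(30), 30 - np.arange(1, 31)]) / 5.0
        x = np.tile(seg, n // 60)
        val = fz.path_linearity(make_traj(x, np.zeros(n)), self.IV)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_semicircular_window(self):
        # one exact semicircle per window; displacement = diameter,
        # distance -> half circumference, so the ratio -> 2/pi.  A high frame
        # rate keeps the polyline within 1e-6 of the continuous arc.
        fps, window_s, n_win = 1500.0, 2.0, 5
        W = int(fps * window_s)
        r = 5.0
        theta = np.pi * np.arange(W) / (W - 1)
        arc_x = r * (1 - np.cos(theta))  # 0 -> 2r
        arc_y = r * np.sin(theta)
        xs, ys = [], []
        for k in range(n_win):
            xs.append(2 * r * k + arc_x)
            ys.append(arc_y if k % 2 == 0 else -arc_y)
        traj = make_traj(np.concatenate(xs), np.concatenate(ys), fps=fps)
        iv = AnalysisInterval("obs", 0.0, n_win * window_s)
        val = fz.path_linearity(traj, iv, window_s=window_s)
        assert val == pytest.approx(2.0 / np.pi, abs=1e-6)

    def test_never_exceeds_one(self, arena):
        for seed in range(5):
            lab = fz.generate_trajectory(fz.scenario("glial_oe_like"), 60.0,
                                         arena, seed=seed)
            iv = AnalysisInterval("all", 0.0, 60.0)
            val = fz.path_linearity(lab.trajectory, iv)
            assert val is None or 0.0 <= val <= 1.0


def _speed_profile_traj(speeds, fps=30.0):
    """Trajectory moving along +x with the given per-frame speeds (mm/s)."""
    steps = np.concatenate([[0.0], np.asarray(speeds, float)[:-1] / fps])
    return make_traj(np.cumsum(steps), np.zeros(len(steps)), fps=fps)


class TestHighVelocityEvents:
    IV = AnalysisInterval("obs", 0.0, 20.0)

    def test_constant_speed_no_events(self):
        traj = line_traj(5.0, 20.0)
        assert fz.high_velocity_events(traj, self.IV) == 0

    def test_single_spike_counts_once(self):
        # full-recording baseline: a brief spike in a long recording barely
        # moves the mean + 10 SD threshold
        speeds = np.full(18000, 1.0)
        speeds[300:320] = 100.0
        traj = _speed_profile_traj(speeds)
        assert fz.high_velocity_events(traj, self.IV, smoothing_frames=1) == 1

    def test_debounce_merges_split_spike(self):
        speeds = np.full(18000, 1.0)
        speeds[300:310] = 100.0
        speeds[310:312] = 1.0  # 2-frame dip, below the 10-frame debounce gap
        speeds[312:322] = 100.0
        traj = _speed_profile_traj(speeds)
        assert fz.high_velocity_events(traj, self.IV, smoothing_frames=1) == 1

    def test_count_invariant_under_time_shift(self):
        speeds = np.full(18000, 1.0)
        speeds[200:215] = 80.0
        speeds[500:512] = 80.0
        early = _speed_profile_traj(speeds)
        late = _speed_profile_traj(np.roll(speeds, 300))
        iv_all = AnalysisInterval("all", 0.0, 600.0)
        assert (fz.high_velocity_events(early, iv_all, smoothing_frames=1)
                == fz.high_velocity_events(late, iv_all, smoothing_frames=1))


class TestRigidMotionInvariance:
    def test_total_distance_under_rotation_translation(self, arena, big_arena):
        lab = fz.generate_trajectory(fz.scenario("control_like"), 60.0, arena,
                                     seed=11)
        traj = lab.trajectory
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy = traj.xy @ R.T + np.array([5.0, -3.0])
        moved = make_traj(xy[:, 0], xy[:, 1])
        iv = AnalysisInterval("all", 0.0, 60.0)
        d0 = fz.locomotion_summary(traj, iv, big_arena).total_distance_mm
        d1 = fz.locomotion_summary(moved, iv, big_arena).total_distance_mm
        assert d1 == pytest.approx(d0, abs=1e-9)
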