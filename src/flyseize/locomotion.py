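"""Open-field locomotion metrics.

Per-fly, per-interval statistics of centroid trajectories: average speed,
percent active time, total distance, path linearity (displacement/distance over
2-s windows), percent time in the arena center (thigmotaxis readout) and
high-velocity event counts (wing-buzz correlate: speed exceeding the fly's
whole-recording mean by ``k_sd`` standard deviations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .arena import AnalysisInterval, ArenaSpec
from .trajectory import Trajectory, interval_mask, speed_series

__all__ = [
    "LocomotionSummary",
    "path_linearity",
    "high_velocity_events",
    "locomotion_summary",
]


@dataclass(frozen=True)
class LocomotionSummary:
    """All per-interval open-field measures for one fly."""

    fly_id: str
    interval: str
    average_speed_mm_s: float
    percent_active_time: float
    total_distance_mm: float
    path_linearity: Optional[float]  # None when no window clears the movement floor
    percent_time_in_center: float
    high_velocity_event_count: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_active_time <= 100.0 + 1e-9:
            raise ValueError("percent_active_time out of [0, 100]")
        if not 0.0 <= self.percent_time_in_center <= 100.0 + 1e-9:
            raise ValueError("percent_time_in_center out of [0, 100]")
        if self.total_distance_mm < 0:
            raise ValueError("total_distance must be >= 0")
        if self.path_linearity is not None and not -1e-9 <= self.path_linearity <= 1 + 1e-9:
            raise ValueError("path_linearity out of [0, 1]")
        if self.high_velocity_event_count < 0:
            raise ValueError("high_velocity_event_count must be >= 0")


def path_linearity(
    traj: Trajectory,
    interval: AnalysisInterval,
    window_s: float = 2.0,
    movement_floor_mm: float = 0.5,
) -> Optional[float]:
    """Mean displacement/distance ratio over consecutive ``window_s`` windows.

    The interval is split into non-overlapping windows; each contributes
    ``|end - start| / path length``.  Windows whose path length is below
    ``movement_floor_mm`` are excluded (a motionless window is 0/0); returns
    ``None`` if no window remains.  The triangle inequality bounds every ratio
    by 1, attained only for collinear monotone motion.
    """
    if interval.duration_s < window_s:
        raise ValueError("interval shorter than the linearity window")
    m = interval_mask(traj, interval)
    idx = np.flatnonzero(m)
    W = int(round(window_s * traj.fps))
    xy = traj.xy[idx]
    n_win = len(xy) // W
    ratios = []
    for k in range(n_win):
        w = xy[k * W:(k + 1) * W]
        path = float(np.hypot(np.diff(w[:, 0]), np.diff(w[:, 1])).sum())
        if path < movement_floor_mm:
            continue
        disp = float(np.hypot(*(w[-1] - w[0])))
        ratios.append(min(disp / path, 1.0))
    if not ratios:
        return None
    return float(np.mean(ratios))


def high_velocity_events(
    traj: Trajectory,
    interval: AnalysisInterval,
    k_sd: float = 10.0,
    debounce_frames: int = 10,
    smoothing_frames: int = 5,
) -> int:
    """Count rising crossings of ``mean + k_sd*SD`` of the fly's speed.

    The mean/SD baseline uses the *entire* recording, not just the interval;
    crossings within the interval closer than ``debounce_frames`` are merged
    into one event.
    """
    if len(traj) < 2:
        raise ValueError("zero-length recording")
    speed = speed_series(traj, smoothing_frames=smoothing_frames)
    threshold = float(speed.mean() + k_sd * speed.std())
    m = interval_mask(traj, interval)
    s = speed[m]
    above = s > threshold
    if not above.any():
        return 0
    rising = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    falling = np.flatnonzero(~above & np.concatenate([[False], above[:-1]]))
    if len(falling) < len(rising):
        falling = np.concatenate([falling, [len(s)]])
    count = 1
    for i in range(1, len(rising)):
        # merge when the below-threshold dip is shorter than the debounce gap
        if rising[i] - falling[i - 1] >= debounce_frames:
            count += 1
    return count


def locomotion_summary(
    traj: Trajectory,
    interval: AnalysisInterval,
    arena: ArenaSpec,
    active_speed_threshold: float = 1.0,
    smoothing_frames: int = 5,
    k_sd: float = 10.0,
    debounce_frames: int = 10,
    linearity_window_s: float = 2.0,
    movement_floor_mm: float = 0.5,
) -> LocomotionSummary:
    """Compute every open-field measure for one fly over one analysis window.

    ``active_speed_threshold`` (mm/s) defines "percent active time"; the
    default 1 mm/s treats sub-millimetre jitter as inactivity.
    """
    m = interval_mask(traj, interval)
    speed = speed_series(traj, smoothing_frames=smoothing_frames)[m]
    idx = np.flatnonzero(m)
    xy = traj.xy[idx]
    # distance: sum of frame-to-frame displacements within the interval
    total_distance = float(np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1])).sum())
    in_center = arena.in_center(xy[:, 0], xy[:, 1])
    return LocomotionSummary(
        fly_id=traj.fly_id,
        interval=interval.name,
        average_speed_mm_s=float(speed.mean()),
        percent_active_time=float(100.0 * (speed > active_speed_threshold).mean()),
        total_distance_mm=total_distance,
        path_linearity=path_linearity(
            traj, interval, window_s=linearity_window_s,
            movement_floor_mm=movement_floor_mm,
        ),
        percent_time_in_center=float(100.0 * in_center.mean()),
        high_velocity_event_count=high_velocity_events(
            traj, interval, k_sd=k_sd, debounce_frames=debounce_frames,
            smoothing_frames=smoothing_frames,
        ),
    )
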