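"""Centroid-trajectory container, file I/O and per-frame speed.

Canonical trajectory dialect: UTF-8 CSV with header
``frame,time_s,fly_id,x_mm,y_mm``, one row per fly per frame, as produced by an
upstream video tracker running at a fixed frame rate (30 fps in the assays this
package targets).  A tab-separated pixel-unit export can be read by passing
``sep="\\t"`` and ``units="px"`` with a calibration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .arena import AnalysisInterval, ArenaSpec

__all__ = ["Trajectory", "load_trajectories", "write_trajectories", "speed_series",
           "interval_mask"]

logger = logging.getLogger(__name__)

_TIME_TOL = 1e-6


@dataclass
class Trajectory:
    """Uniformly sampled centroid time series for one fly.

    ``gap_mask`` flags frames where tracking was lost and coordinates were
    filled by linear interpolation.
    """

    fly_id: str
    fps: float
    time_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    gap_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.x_mm = np.asarray(self.x_mm, float)
        self.y_mm = np.asarray(self.y_mm, float)
        n = len(self.time_s)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(n, dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, bool)
        if not (len(self.x_mm) == len(self.y_mm) == len(self.gap_mask) == n):
            raise ValueError("trajectory arrays must share a common length")
        if n < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ValueError("non-monotone time")
        if np.any(np.abs(dt - 1.0 / self.fps) > _TIME_TOL):
            raise ValueError("time step inconsistent with declared fps")
        if not (np.all(np.isfinite(self.x_mm)) and np.all(np.isfinite(self.y_mm))):
            raise ValueError("coordinates must be finite after gap fill")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return np.column_stack([self.x_mm, self.y_mm])


def interval_mask(traj: Trajectory, interval: AnalysisInterval) -> np.ndarray:
    """Boolean mask of frames with time in [start_s, end_s)."""
    m = (traj.time_s >= interval.start_s - _TIME_TOL) & (traj.time_s < interval.end_s - _TIME_TOL)
    if not m.any():
        raise ValueError(
            f"interval {interval.name!r} [{interval.start_s}, {interval.end_s}) "
            "contains no frames of this trajectory"
        )
    return m


def load_trajectories(
    path,
    arena: Optional[ArenaSpec] = None,
    fps: float = 30.0,
    max_gap_s: float = 1.0,
    sep: str = ",",
    units: str = "mm",
    pixels_per_mm: Optional[float] = None,
    origin: str = "center",
) -> List[Trajectory]:
    """Read a multi-fly trajectory file into one :class:`Trajectory` per fly.

    Missing frames are linearly interpolated and flagged in ``gap_mask``.
    A fly whose longest gap exceeds ``max_gap_s`` is rejected with a logged
    reason.  Out-of-arena points are clipped to the boundary with a warning.

    Parameters
    ----------
    units:
        ``"mm"`` (canonical, columns ``x_mm,y_mm``) or ``"px"`` (columns
        ``x_px,y_px``; requires ``pixels_per_mm``, typically with
        ``origin="top_left"`` so coordinates are re-centred on the arena and
        the y axis flipped to point upward).
    """
    df = pd.read_csv(path, sep=sep)
    if units == "px":
        scale = pixels_per_mm or (arena.pixels_per_mm if arena else None)
        if not scale:
            raise ValueError("pixel-unit input requires pixels_per_mm calibration")
        if not {"x_px", "y_px"} <= set(df.columns):
            raise ValueError("pixel dialect requires columns x_px,y_px")
        df = df.rename(columns={"x_px": "x_mm", "y_px": "y_mm"})
        df["x_mm"] = df["x_mm"] / scale
        df["y_mm"] = df["y_mm"] / scale
        if origin == "top_left":
            if arena is None:
                raise ValueError("top-left origin conversion requires an ArenaSpec")
            ext = arena.max_extent_mm
            df["x_mm"] = df["x_mm"] - ext / 2.0 + arena.center_mm[0]
            df["y_mm"] = ext / 2.0 - df["y_mm"] + arena.center_mm[1]
    required = {"frame", "time_s", "fly_id", "x_mm", "y_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("trajectory file contains no rows")

    out: List[Trajectory] = []
    for fly_id, g in df.groupby("fly_id", sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy(dtype=np.int64)
        times = g["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"non-monotone time for fly {fly_id!r}")
        full = np.arange(frames[0], frames[-1] + 1)
        present = np.isin(full, frames)
        max_gap_frames = int(round(max_gap_s * fps))
        if not present.all():
            # longest run of consecutive missing frames
            runs = _missing_runs(present)
            if runs and max(runs) > max_gap_frames:
                logger.warning(
                    "rejecting fly %r: tracking gap of %d frames exceeds %.3g s",
                    fly_id, max(runs), max_gap_s,
                )
                continue
        x = np.interp(full, frames, g["x_mm"].to_numpy(dtype=float))
        y = np.interp(full, frames, g["y_mm"].to_numpy(dtype=float))
        t = times[0] + (full - full[0]) / fps
        gap = ~present
        if arena is not None:
            inside = arena.contains(x, y)
            if not inside.all():
                warnings.warn(
                    f"fly {fly_id!r}: {int((~inside).sum())} out-of-arena points "
                    "clipped to the boundary",
                    stacklevel=2,
                )
                x, y = arena.clip(x, y)
        out.append(Trajectory(str(fly_id), fps, t, x, y, gap))
    if not out:
        raise ValueError("no usable fly trajectories in file")
    return out


def _missing_runs(present: np.ndarray) -> List[int]:
    runs, run = [], 0
    for p in present:
        if p:
            if run:
                runs.append(run)
            run = 0
        else:
            run += 1
    if run:
        runs.append(run)
    return runs


def write_trajectories(path, trajectories: Iterable[Trajectory]) -> None:
    """Write trajectories in the canonical CSV dialect."""
    rows = []
    for traj in trajectories:
        rows.append(pd.DataFrame({
            "frame": np.arange(len(traj)),
            "time_s": traj.time_s,
            "fly_id": traj.fly_id,
            "x_mm": traj.x_mm,
            "y_mm": traj.y_mm,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def speed_series(traj: Trajectory, smoothing_frames: int = 5) -> np.ndarray:
    """Per-frame speed in mm/s.

    ``speed[i] = fps * ||p[i+1] - p[i]||`` with the final frame repeating the
    last value so the length matches the frame count; optionally median
    filtered over ``smoothing_frames`` (odd, >= 1; 1 disables smoothing, which
    otherwise suppresses single-frame tracker jitter).
    """
    if smoothing_frames < 1 or smoothing_frames % 2 == 0:
        raise ValueError("smoothing_frames must be an odd integer >= 1")
    step = np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm))
    speed = np.concatenate([step, step[-1:]]) * traj.fps
    if smoothing_frames > 1:
        speed = median_filter(speed, size=smoothing_frames, mode="nearest")
    return speed
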