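"""Arena geometry and temperature-protocol schedule.

Open-field assays run in small polyacrylate arenas on a temperature-controlled
stage.  Coordinates throughout the package are millimetres with the origin at
the arena centre and y increasing upward; converters from pixel/top-left input
live in the trajectory reader and must be requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = ["ArenaSpec", "Phase", "AnalysisInterval", "ProtocolSchedule"]


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of a behavioral arena.

    The "center region" used for thigmotaxis scoring is the concentric,
    geometrically similar region scaled by ``center_region_fraction`` in
    linear dimension (a disc of half the diameter covers 25 % of the area).
    """

    shape: str = "circular"  # "circular" | "rectangular"
    diameter_mm: Optional[float] = 30.0
    width_mm: Optional[float] = None
    height_mm: Optional[float] = None
    center_mm: Tuple[float, float] = (0.0, 0.0)
    center_region_fraction: float = 0.5
    pixels_per_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.shape not in ("circular", "rectangular"):
            raise ValueError(f"unknown arena shape {self.shape!r}")
        if self.shape == "circular":
            if self.diameter_mm is None or self.diameter_mm <= 0:
                raise ValueError("circular arena requires diameter_mm > 0")
        else:
            if not (self.width_mm and self.height_mm) or self.width_mm <= 0 or self.height_mm <= 0:
                raise ValueError("rectangular arena requires width_mm, height_mm > 0")
        if not 0.0 < self.center_region_fraction < 1.0:
            raise ValueError("center_region_fraction must lie in (0, 1)")
        if self.pixels_per_mm is not None and self.pixels_per_mm <= 0:
            raise ValueError("pixels_per_mm must be > 0")

    # -- geometry helpers -------------------------------------------------
    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the arena."""
        dx = np.asarray(x, float) - self.center_mm[0]
        dy = np.asarray(y, float) - self.center_mm[1]
        if self.shape == "circular":
            return np.hypot(dx, dy) <= self.diameter_mm / 2.0 + 1e-9
        return (np.abs(dx) <= self.width_mm / 2.0 + 1e-9) & (
            np.abs(dy) <= self.height_mm / 2.0 + 1e-9
        )

    def in_center(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the concentric center region."""
        f = self.center_region_fraction
        dx = np.asarray(x, float) - self.center_mm[0]
        dy = np.asarray(y, float) - self.center_mm[1]
        if self.shape == "circular":
            return np.hypot(dx, dy) <= f * self.diameter_mm / 2.0 + 1e-9
        return (np.abs(dx) <= f * self.width_mm / 2.0 + 1e-9) & (
            np.abs(dy) <= f * self.height_mm / 2.0 + 1e-9
        )

    def clip(self, x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Project out-of-arena points onto the boundary."""
        x = np.asarray(x, float).copy()
        y = np.asarray(y, float).copy()
        dx = x - self.center_mm[0]
        dy = y - self.center_mm[1]
        if self.shape == "circular":
            r = np.hypot(dx, dy)
            R = self.diameter_mm / 2.0
            bad = r > R
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(bad & (r > 0), R / np.where(r > 0, r, 1.0), 1.0)
            x = self.center_mm[0] + dx * scale
            y = self.center_mm[1] + dy * scale
        else:
            x = self.center_mm[0] + np.clip(dx, -self.width_mm / 2.0, self.width_mm / 2.0)
            y = self.center_mm[1] + np.clip(dy, -self.height_mm / 2.0, self.height_mm / 2.0)
        return x, y

    @property
    def max_extent_mm(self) -> float:
        if self.shape == "circular":
            return float(self.diameter_mm)
        return float(max(self.width_mm, self.height_mm))


@dataclass(frozen=True)
class Phase:
    """One temperature phase of the assay protocol."""

    name: str  # baseline | ramp | high_temp | return
    start_s: float
    end_s: float
    temperature_C: Tuple[float, float] = (21.0, 21.0)

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"phase {self.name!r}: end_s must exceed start_s")


@dataclass(frozen=True)
class AnalysisInterval:
    """Named half-open analysis window [start_s, end_s)."""

    name: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"interval {self.name!r}: end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered, contiguous temperature phases plus named analysis windows.

    The default mirrors a standardized 10-min open-field assay: 180 s at a
    21 degC baseline, a 90 s ramp, a 120 s high-temperature period (36-39 degC)
    and a 210 s return, with 2-min analysis windows at 30-150 s (baseline) and
    270-390 s (high temperature).
    """

    phases: Tuple[Phase, ...]
    analysis_intervals: Tuple[AnalysisInterval, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        for a, b in zip(self.phases, self.phases[1:]):
            if abs(a.end_s - b.start_s) > 1e-9:
                raise ValueError(
                    f"phases must be contiguous and non-overlapping "
                    f"({a.name!r} ends {a.end_s}, {b.name!r} starts {b.start_s})"
                )
        names = [iv.name for iv in self.analysis_intervals]
        if len(set(names)) != len(names):
            raise ValueError("analysis interval names must be unique")
        for iv in self.analysis_intervals:
            if not any(
                ph.start_s - 1e-9 <= iv.start_s and iv.end_s <= ph.end_s + 1e-9
                for ph in self.phases
            ):
                raise ValueError(
                    f"analysis interval {iv.name!r} does not lie within a single phase"
                )
        for a, b in zip(self.analysis_intervals, self.analysis_intervals[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(
                    f"analysis intervals overlap ({a.name!r} and {b.name!r})"
                )

    @classmethod
    def default(cls) -> "ProtocolSchedule":
        return cls(
            phases=(
                Phase("baseline", 0.0, 180.0, (21.0, 21.0)),
                Phase("ramp", 180.0, 270.0, (21.0, 36.0)),
                Phase("high_temp", 270.0, 390.0, (36.0, 39.0)),
                Phase("return", 390.0, 600.0, (39.0, 21.0)),
            ),
            analysis_intervals=(
                AnalysisInterval("baseline", 30.0, 150.0),
                AnalysisInterval("high_temp", 270.0, 390.0),
            ),
        )

    @property
    def total_duration_s(self) -> float:
        return self.phases[-1].end_s

    def interval(self, name: str) -> AnalysisInterval:
        for iv in self.analysis_intervals:
            if iv.name == name:
                return iv
        raise KeyError(f"no analysis interval named {name!r}")

    def phase_at(self, t: float) -> Phase:
        for ph in self.phases:
            if ph.start_s - 1e-9 <= t < ph.end_s:
                return ph
        if abs(t - self.phases[-1].end_s) < 1e-9:
            return self.phases[-1]
        raise ValueError(f"time {t} s outside protocol (0-{self.total_duration_s} s)")

    def phase_names_at(self, times: Sequence[float]) -> np.ndarray:
        """Vectorized phase lookup (clamped to the protocol extent)."""
        t = np.asarray(times, float)
        out = np.empty(t.shape, dtype=object)
        out[:] = self.phases[-1].name
        for ph in reversed(self.phases):
            out[t < ph.end_s] = ph.name
        out[t < self.phases[0].start_s] = self.phases[0].name
        return out
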