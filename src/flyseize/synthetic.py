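"""Ground-truth-labeled synthetic data generators.

Every downstream stage (locomotion metrics, HMM classifier, spike/burst
analysis, survival statistics) is testable against these generators without
any recorded data.  The generators target the *statistical structure* of
open-field and tethered-fly recordings from glial- vs neuronal-overexpression
seizure models, not biophysical realism:

* locomotion — a semi-Markov (explicit dwell-time) three-state process:
  walking (correlated random walk reflected at the arena wall), brief pauses
  (near-zero jitter) and prolonged immobilization (larger residual twitch
  jitter, long dwell).  Seizure-like scenarios add high-velocity "wing buzz"
  events and low-linearity "spin" bouts during the high-temperature phase and
  enter immobilization with a constant hazard, so expected immobilized time
  has a closed form used by the tests.
* spikes — sparse irregular grooming bouts (<1 s, instantaneous rates
  approaching 100 Hz) plus, in seizure mode, sustained rhythmic bursts
  (5-15 s at ~7 Hz, small ISI jitter) copied to both recording channels with
  per-spike bilateral jitter.
* survival — constant-hazard (exponential) death days censored at a 14-d
  horizon.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .arena import ArenaSpec, ProtocolSchedule
from .hmm import STATES
from .spikes import Burst, SpikeTrain, VoltageTrace
from .trajectory import Trajectory

__all__ = [
    "StatePhaseParams", "SyntheticScenario", "LabeledTrajectory", "FlyRecord",
    "CohortDataset", "scenario", "SCENARIOS", "generate_trajectory",
    "generate_spike_train", "synthesize_voltage", "generate_cohort",
    "generate_survival", "expected_immobilized_s",
]

logger = logging.getLogger(__name__)

_WALK, _PAUSE, _IMMOB = (STATES.index("walking"), STATES.index("pausing"),
                         STATES.index("immobilized"))


@dataclass(frozen=True)
class StatePhaseParams:
    """Dwell/hazard structure for one protocol phase category."""

    walk_dwell_s: float = 4.0        # mean walking bout (exponential)
    pause_dwell_s: float = 0.8      # mean pause bout (exponential)
    max_pause_s: Optional[float] = None  # truncate pauses (control-like: <1.5 s)
    immob_entry_rate_hz: float = 0.0     # constant hazard of entering immobilization
    hv_event_rate_hz: float = 0.0        # wing-buzz-like high-velocity events
    spin_bout_prob: float = 0.0          # walking bout replaced by a spin bout

    def __post_init__(self) -> None:
        if self.walk_dwell_s <= 0 or self.pause_dwell_s <= 0:
            raise ValueError("dwell means must be > 0")
        if min(self.immob_entry_rate_hz, self.hv_event_rate_hz) < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.spin_bout_prob <= 1.0:
            raise ValueError("spin_bout_prob must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one genotype-like group.

    Kinematic amplitudes are in mm (per-frame jitter SDs) and mm/s (walking
    speed); dwell means in seconds; rates in Hz; the survival hazard in 1/day.
    Defaults for the seizure-like preset are anchored to headline statistics
    of the assays this package emulates (immobilized dwell tens of seconds,
    bursts 5-15 s at ~7 Hz with CV2 ~0.04, 10-d median lifespan) without any
    claim of equivalence to real flies.
    """

    name: str
    # walking kinematics
    walk_speed_mean_mm_s: float = 8.0
    walk_speed_sd_mm_s: float = 2.0
    heading_sd_rad: float = 0.25
    # low-motion kinematics (per-frame displacement SD around an anchor);
    # immobilization is distinguished by slightly larger residual jitter plus
    # sparse twitch events, not by sustained movement
    pause_jitter_sd_mm: float = 0.015
    immob_jitter_sd_mm: float = 0.03
    twitch_rate_hz: float = 1.5
    twitch_amp_mm: float = 0.6
    immob_dwell_s: float = 50.0
    # phase-specific dwell/hazard structure
    baseline: StatePhaseParams = field(default_factory=StatePhaseParams)
    high_temp: StatePhaseParams = field(default_factory=StatePhaseParams)
    # seizure-event kinematics
    hv_speed_mm_s: float = 75.0
    hv_duration_frames: int = 4
    spin_radius_mm: float = 1.0
    spin_rev_per_s: float = 2.0
    spin_duration_s: float = 2.0
    # spike-train structure
    groom_bout_rate_hz: float = 0.05
    groom_bout_dur_s: Tuple[float, float] = (0.2, 0.8)
    groom_rate_hz: float = 60.0
    groom_min_isi_s: float = 0.008
    burst_rate_hz: float = 0.0           # burst-episode occurrence rate
    burst_duration_s: Tuple[float, float] = (5.0, 15.0)
    burst_intra_rate_hz: float = 7.0
    burst_isi_cv: float = 0.04
    bilateral_jitter_ms: float = 10.0
    # survival
    hazard_per_day: float = 0.0

    def __post_init__(self) -> None:
        if self.immob_dwell_s <= 0:
            raise ValueError("immob_dwell_s must be > 0")
        for r in (self.groom_bout_rate_hz, self.burst_rate_hz, self.twitch_rate_hz,
                  self.hazard_per_day):
            if r < 0:
                raise ValueError("rates must be >= 0")

    def phase_params(self, category: str) -> StatePhaseParams:
        return self.high_temp if category == "high_temp" else self.baseline


def expected_immobilized_s(scenario: SyntheticScenario, duration_s: float,
                           phase: str = "high_temp") -> float:
    """Closed-form expected immobilized time over a window of that phase.

    The generator enters immobilization with constant hazard ``a`` while
    active and leaves with rate ``b = 1/immob_dwell_s``, i.e. a two-level
    continuous-time Markov chain started active, whose expected occupancy is
    ``(a/(a+b)) * (T - (1 - e^{-(a+b)T})/(a+b))``.
    """
    a = scenario.phase_params(phase).immob_entry_rate_hz
    b = 1.0 / scenario.immob_dwell_s
    if a == 0:
        return 0.0
    s = a + b
    return (a / s) * (duration_s - (1.0 - math.exp(-s * duration_s)) / s)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def _control() -> SyntheticScenario:
    ctrl_phase = StatePhaseParams(walk_dwell_s=4.0, pause_dwell_s=0.7,
                                  max_pause_s=1.4)
    return SyntheticScenario(
        name="control_like",
        baseline=ctrl_phase,
        high_temp=StatePhaseParams(walk_dwell_s=3.0, pause_dwell_s=0.7,
                                   max_pause_s=1.4),
        hazard_per_day=0.01,
    )


def _glial() -> SyntheticScenario:
    return SyntheticScenario(
        name="glial_oe_like",
        walk_speed_mean_mm_s=5.0,
        heading_sd_rad=0.45,
        immob_dwell_s=50.0,
        baseline=StatePhaseParams(walk_dwell_s=3.0, pause_dwell_s=1.0,
                                  immob_entry_rate_hz=0.002),
        high_temp=StatePhaseParams(walk_dwell_s=2.0, pause_dwell_s=1.0,
                                   immob_entry_rate_hz=0.025,
                                   hv_event_rate_hz=0.08, spin_bout_prob=0.15),
        burst_rate_hz=1.0 / 40.0,
        hazard_per_day=math.log(2) / 10.0,  # configured 10-d median lifespan
    )


def _neuronal() -> SyntheticScenario:
    return SyntheticScenario(
        name="neuronal_oe_like",
        walk_speed_mean_mm_s=6.0,
        immob_dwell_s=15.0,
        baseline=StatePhaseParams(walk_dwell_s=3.5, pause_dwell_s=0.9),
        high_temp=StatePhaseParams(walk_dwell_s=2.5, pause_dwell_s=1.0,
                                   immob_entry_rate_hz=0.006),
        hazard_per_day=math.log(2) / 2.0,  # configured 2-d median lifespan
    )


def _well_separated() -> SyntheticScenario:
    """Well-separated state kinematics for classifier scoring: fast,
    persistent walking, multi-second pauses and long twitchy immobilization,
    so each 2-s window is dominated by a single regime."""
    phase = StatePhaseParams(walk_dwell_s=10.0, pause_dwell_s=14.0,
                             immob_entry_rate_hz=0.02)
    return SyntheticScenario(
        name="well_separated",
        walk_speed_mean_mm_s=10.0,
        walk_speed_sd_mm_s=2.0,
        pause_jitter_sd_mm=0.01,
        immob_jitter_sd_mm=0.05,
        twitch_rate_hz=2.0,
        immob_dwell_s=40.0,
        baseline=phase,
        high_temp=phase,
        burst_rate_hz=1.0 / 40.0,
    )


SCENARIOS = {
    "control_like": _control,
    "glial_oe_like": _glial,
    "neuronal_oe_like": _neuronal,
    "well_separated": _well_separated,
}


def scenario(name: str) -> SyntheticScenario:
    """Return a named scenario preset."""
    try:
        return SCENARIOS[name]()
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; "
                       f"choose from {sorted(SCENARIOS)}") from None


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

@dataclass
class LabeledTrajectory:
    """Trajectory plus per-frame ground-truth state and seizure-event log."""

    trajectory: Trajectory
    labels: np.ndarray           # int codes into hmm.STATES per frame
    events: List[Dict]           # {"kind", "time_s", "end_s"} entries
    scenario_name: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.trajectory):
            raise ValueError("labels must cover every frame")


def generate_trajectory(
    scen: SyntheticScenario,
    duration_s: float,
    arena: ArenaSpec,
    seed: int,
    protocol: Optional[ProtocolSchedule] = None,
    fps: float = 30.0,
) -> LabeledTrajectory:
    """Simulate one fly's centroid trajectory with ground-truth labels.

    The state process is semi-Markov: walking bouts (exponential dwell)
    alternate with pauses, a constant phase-specific hazard interrupts active
    periods with immobilization, and seizure-like scenarios overlay
    high-velocity events and spin bouts while active at high temperature.
    Identical (parameters, seed) give bit-identical output.
    """
    if duration_s < 10.0:
        raise ValueError("duration must be >= 10 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    dt = 1.0 / fps
    R_eff = arena.max_extent_mm / 2.0 - 0.5  # wall margin, mm
    if scen.walk_speed_mean_mm_s * dt > arena.max_extent_mm:
        raise ValueError("walking kinematics exceed the arena size per frame")

    if protocol is not None:
        cat = np.where(
            protocol.phase_names_at(np.arange(n) * dt) == "high_temp",
            "high_temp", "baseline")
    else:
        cat = np.full(n, "baseline", dtype=object)

    x = np.empty(n)
    y = np.empty(n)
    labels = np.empty(n, dtype=np.int8)
    events: List[Dict] = []

    r0 = 0.5 * R_eff * math.sqrt(rng.uniform())
    a0 = rng.uniform(0, 2 * math.pi)
    px, py = (arena.center_mm[0] + r0 * math.cos(a0),
              arena.center_mm[1] + r0 * math.sin(a0))
    heading = rng.uniform(0, 2 * math.pi)

    def walk_frames(k: int, start: int, spin: bool) -> None:
        nonlocal px, py, heading
        pp = scen.phase_params(cat[start])
        hv_left = 0
        if spin:
            # tight circle around the current anchor: low path linearity
            cx = px - scen.spin_radius_mm * math.cos(heading)
            cy = py - scen.spin_radius_mm * math.sin(heading)
            omega = 2 * math.pi * scen.spin_rev_per_s * dt
            phi = heading
            for i in range(k):
                phi += omega
                px = cx + scen.spin_radius_mm * math.cos(phi)
                py = cy + scen.spin_radius_mm * math.sin(phi)
                x[start + i], y[start + i] = px, py
                labels[start + i] = _WALK
            return
        dhead = rng.normal(0.0, scen.heading_sd_rad, size=k)
        speeds = np.clip(
            rng.normal(scen.walk_speed_mean_mm_s, scen.walk_speed_sd_mm_s, size=k),
            0.0, None)
        hv_hits = (rng.uniform(size=k) < pp.hv_event_rate_hz * dt)
        for i in range(k):
            f = start + i
            if hv_left == 0 and hv_hits[i]:
                hv_left = scen.hv_duration_frames
                events.append({"kind": "high_velocity", "time_s": f * dt,
                               "end_s": (f + scen.hv_duration_frames) * dt})
            speed = scen.hv_speed_mm_s if hv_left > 0 else speeds[i]
            if hv_left > 0:
                hv_left -= 1
            heading += dhead[i]
            nx = px + speed * dt * math.cos(heading)
            ny = py + speed * dt * math.sin(heading)
            dxc, dyc = nx - arena.center_mm[0], ny - arena.center_mm[1]
            if math.hypot(dxc, dyc) > R_eff:
                # bounce: head back toward the centre with some scatter
                heading = math.atan2(-dyc, -dxc) + rng.normal(0.0, 0.3)
                nx = px + speed * dt * math.cos(heading)
                ny = py + speed * dt * math.sin(heading)
                dxc, dyc = nx - arena.center_mm[0], ny - arena.center_mm[1]
                rr = math.hypot(dxc, dyc)
                if rr > R_eff:
                    nx = arena.center_mm[0] + dxc * R_eff / rr
                    ny = arena.center_mm[1] + dyc * R_eff / rr
            px, py = nx, ny
            x[f], y[f] = px, py
            labels[f] = _WALK

    def still_frames(k: int, start: int, state: int) -> None:
        nonlocal px, py
        sd = scen.pause_jitter_sd_mm if state == _PAUSE else scen.immob_jitter_sd_mm
        off = rng.normal(0.0, sd, size=(k, 2))
        if state == _IMMOB and scen.twitch_rate_hz > 0:
            tw = rng.uniform(size=k) < scen.twitch_rate_hz * dt
            off[tw] += rng.normal(0.0, scen.twitch_amp_mm, size=(int(tw.sum()), 2))
        xs = np.clip(px + off[:, 0], None, None)
        ys = py + off[:, 1]
        xs, ys = arena.clip(xs, ys)
        x[start:start + k] = xs
        y[start:start + k] = ys
        labels[start:start + k] = state

    frame = 0
    state = _WALK
    while frame < n:
        pp = scen.phase_params(cat[frame])
        if state == _WALK:
            dwell = rng.exponential(pp.walk_dwell_s)
            spin = pp.spin_bout_prob > 0 and rng.uniform() < pp.spin_bout_prob
            if spin:
                dwell = scen.spin_duration_s
        elif state == _PAUSE:
            dwell = rng.exponential(pp.pause_dwell_s)
            if pp.max_pause_s is not None:
                dwell = min(dwell, pp.max_pause_s)
            spin = False
        else:
            dwell = rng.exponential(scen.immob_dwell_s)
            spin = False
        # constant-hazard interruption of active bouts by immobilization
        interrupted = False
        if state != _IMMOB and pp.immob_entry_rate_hz > 0:
            entry = rng.exponential(1.0 / pp.immob_entry_rate_hz)
            if entry < dwell:
                dwell = entry
                interrupted = True
        k = max(1, int(round(dwell / dt)))
        k = min(k, n - frame)
        if state == _WALK:
            if spin and k > 1:
                events.append({"kind": "spin", "time_s": frame * dt,
                               "end_s": (frame + k) * dt})
            walk_frames(k, frame, spin)
        else:
            still_frames(k, frame, state)
        frame += k
        if interrupted:
            state = _IMMOB
        elif state == _WALK:
            state = _PAUSE
        else:
            state = _WALK

    t = np.arange(n) / fps
    traj = Trajectory(f"{scen.name}-{seed}", fps, t, x, y)
    return LabeledTrajectory(traj, labels, events, scen.name, seed)


# ---------------------------------------------------------------------------
# spike trains and voltage
# ---------------------------------------------------------------------------

def generate_spike_train(
    scen: SyntheticScenario,
    duration_s: float,
    seed: int,
    channels: Tuple[str, str] = ("L_DLM", "R_DLM"),
) -> Tuple[Dict[str, SpikeTrain], List[Burst]]:
    """Simulate bilateral DLM spike trains with ground-truth burst intervals.

    Grooming bouts are generated independently per channel; seizure bursts
    (if ``burst_rate_hz > 0``) are generated once and copied to both channels
    with per-spike bilateral jitter, so bursts are near-synchronous across
    channels.  Bursts are kept fully inside the recording and separated by at
    least 2 s; grooming bouts are suppressed within 1 s of a burst (a seizing
    fly does not groom mid-discharge).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)

    # -- shared seizure bursts ------------------------------------------
    truth: List[Burst] = []
    burst_spikes: List[np.ndarray] = []
    if scen.burst_rate_hz > 0:
        t = rng.exponential(1.0 / scen.burst_rate_hz)
        last_end = -math.inf
        while t < duration_s:
            dur = rng.uniform(*scen.burst_duration_s)
            if t >= last_end + 2.0 and t + dur <= duration_s:
                mean_isi = 1.0 / scen.burst_intra_rate_hz
                n_isi = int(dur / mean_isi) + 10
                isis = mean_isi * np.clip(
                    1.0 + scen.burst_isi_cv * rng.normal(size=n_isi), 0.2, None)
                times = t + np.concatenate([[0.0], np.cumsum(isis)])
                times = times[times <= t + dur]
                if len(times) >= 2:
                    burst_spikes.append(times)
                    truth.append(Burst(float(times[0]), float(times[-1]),
                                       len(times),
                                       (len(times) - 1) / float(times[-1] - times[0])))
                    last_end = t + dur
            t += rng.exponential(1.0 / scen.burst_rate_hz)
    shared = np.concatenate(burst_spikes) if burst_spikes else np.array([])

    # -- per-channel grooming bouts + jittered copies of the bursts ------
    jitter_s = scen.bilateral_jitter_ms / 1000.0
    out: Dict[str, SpikeTrain] = {}
    for ch in channels:
        groom: List[float] = []
        if scen.groom_bout_rate_hz > 0:
            t = rng.exponential(1.0 / scen.groom_bout_rate_hz)
            while t < duration_s:
                end = t + rng.uniform(*scen.groom_bout_dur_s)
                in_burst = any(b.start_s - 1.0 <= end and t <= b.end_s + 1.0
                               for b in truth)
                if not in_burst:
                    s = t
                    while s < min(end, duration_s):
                        groom.append(s)
                        s += max(scen.groom_min_isi_s,
                                 rng.exponential(1.0 / scen.groom_rate_hz))
                t = end + rng.exponential(1.0 / scen.groom_bout_rate_hz)
        times = np.array(groom)
        if len(shared):
            jittered = shared + rng.normal(0.0, jitter_s, size=len(shared))
            times = np.concatenate([times, jittered])
        times = np.sort(times)
        times = times[(times >= 0) & (times < duration_s)]
        if len(times) > 1:  # enforce a 1-ms floor between spikes
            keep = np.concatenate([[True], np.diff(times) > 1e-3])
            times = times[keep]
        out[ch] = SpikeTrain(ch, times, 0.0, duration_s)
    return out, truth


def synthesize_voltage(
    train: SpikeTrain,
    sampling_rate: float = 10_000.0,
    snr: float = 8.0,
    seed: int = 0,
) -> VoltageTrace:
    """Render a spike train as a noisy voltage trace.

    Each spike contributes a biphasic waveform (positive crest peaking at the
    spike time, amplitude 1) and Gaussian noise of SD ``1/snr`` is added
    (``snr = inf`` for a noiseless trace).  Overlapping waveforms sum, with a
    log entry.
    """
    if sampling_rate < 1000:
        raise ValueError("sampling_rate must be >= 1000 Hz")
    rng = np.random.default_rng(seed)
    n = int(round((train.t1 - train.t0) * sampling_rate)) + 1
    # biphasic template: Gaussian crest followed by a shallower trough
    tt = np.arange(-0.0015, 0.0045, 1.0 / sampling_rate)
    wave = (np.exp(-0.5 * (tt / 0.0004) ** 2)
            - 0.4 * np.exp(-0.5 * ((tt - 0.0015) / 0.0008) ** 2))
    wave /= wave.max()
    centre = int(np.argmax(wave))
    v = np.zeros(n)
    idx = np.round((train.times - train.t0) * sampling_rate).astype(int)
    if len(idx) > 1 and np.any(np.diff(idx) < len(wave)):
        logger.info("channel %s: overlapping spike waveforms summed", train.channel)
    for i in idx:
        lo = i - centre
        hi = lo + len(wave)
        wlo = max(0, -lo)
        whi = len(wave) - max(0, hi - n)
        v[max(0, lo):min(n, hi)] += wave[wlo:whi]
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        v = v + rng.normal(0.0, 1.0 / snr, size=n)
    return VoltageTrace(train.channel, sampling_rate, v)


# ---------------------------------------------------------------------------
# cohorts and survival
# ---------------------------------------------------------------------------

@dataclass
class FlyRecord:
    """One simulated fly: trajectory + spike trains + ground truth."""

    fly_id: str
    group: str
    labeled: LabeledTrajectory
    spike_trains: Optional[Dict[str, SpikeTrain]]
    burst_truth: Optional[List[Burst]]
    seed: int


@dataclass
class CohortDataset:
    """A labeled multi-group cohort with a reproducible manifest."""

    records: List[FlyRecord]
    master_seed: int

    def manifest(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            imm = float((r.labeled.labels == _IMMOB).sum()
                        / r.labeled.trajectory.fps)
            rows.append({
                "fly_id": r.fly_id,
                "group": r.group,
                "seed": r.seed,
                "n_frames": len(r.labeled.trajectory),
                "true_immobilized_s": imm,
                "n_events": len(r.labeled.events),
                "n_true_bursts": len(r.burst_truth) if r.burst_truth is not None else 0,
            })
        return pd.DataFrame(rows)

    def group(self, name: str) -> List[FlyRecord]:
        return [r for r in self.records if r.group == name]


def _child_seed(master: int, index: int) -> int:
    return int((master * 1_000_003 + 7919 * index + 1) % (2 ** 31 - 1))


def generate_cohort(
    scenarios: Mapping[str, SyntheticScenario],
    n_per_group: int,
    seed: int,
    duration_s: float = 600.0,
    arena: Optional[ArenaSpec] = None,
    protocol: Optional[ProtocolSchedule] = None,
    fps: float = 30.0,
    with_spikes: bool = True,
    spike_duration_s: float = 240.0,
) -> CohortDataset:
    """Simulate a multi-group cohort with per-fly seeds derived from ``seed``."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    names = list(scenarios)
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names")
    arena = arena or ArenaSpec()
    records: List[FlyRecord] = []
    idx = 0
    for group in names:
        scen = scenarios[group]
        for j in range(n_per_group):
            s = _child_seed(seed, idx)
            idx += 1
            lab = generate_trajectory(scen, duration_s, arena, s,
                                      protocol=protocol, fps=fps)
            fly_id = f"{group}_{j:03d}"
            lab.trajectory.fly_id = fly_id
            trains, truth = (None, None)
            if with_spikes:
                trains, truth = generate_spike_train(scen, spike_duration_s,
                                                     _child_seed(seed, 10_000 + idx))
            records.append(FlyRecord(fly_id, group, lab, trains, truth, s))
    return CohortDataset(records, seed)


def generate_survival(
    hazard_per_day: Mapping[str, float],
    n: int,
    seed: int,
    horizon_d: float = 14.0,
) -> pd.DataFrame:
    """Exponential survival table censored at the observation horizon.

    Columns: ``fly, group, day, event`` (event 0 = censored at the horizon).
    A hazard of ln(2)/m gives a configured median lifespan of m days.
    """
    for g, h in hazard_per_day.items():
        if h < 0:
            raise ValueError(f"hazard for group {g!r} must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group in hazard_per_day:
        h = hazard_per_day[group]
        death = (rng.exponential(1.0 / h, size=n) if h > 0
                 else np.full(n, np.inf))
        day = np.minimum(death, horizon_d)
        event = (death <= horizon_d).astype(int)
        for i in range(n):
            rows.append({"fly": f"{group}_{i:04d}", "group": group,
                         "day": float(day[i]), "event": int(event[i])})
    return pd.DataFrame(rows)
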