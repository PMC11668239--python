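"""End-to-end orchestration: simulate -> metrics -> classify -> stats -> report.

Runs are single-process and deterministic: re-running with the same config and
seed reproduces every numeric output bit-identically.  Every report bundle is
written as plain data tables plus a manifest (config hash, seed, software
version) sufficient to regenerate the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .arena import AnalysisInterval
from .config import ConfigError, RunConfig
from .hmm import (HmmModel, FeatureModel, cumulative_onset_curve, decode_states,
                  immobilization_summary, load_model, save_model,
                  train_behavior_classifier)
from .locomotion import locomotion_summary
from .spikes import (BurstRegion, burst_synchrony, count_bursts, cv2_series,
                     overall_firing_frequency, read_spike_trains)
from .stats import GroupedMeasurements, kruskal_wallis_posthoc
from .synthetic import SCENARIOS, generate_cohort, scenario
from .trajectory import Trajectory, load_trajectories

__all__ = ["run_behavior_analysis", "run_ephys_analysis", "ReportBundle"]

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    """In-memory result of a pipeline run (also written under out_dir)."""

    tables: Dict[str, pd.DataFrame]
    stats: Dict
    manifest: Dict


def _manifest(config: RunConfig, kind: str) -> Dict:
    return {
        "kind": kind,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
    }


def _write(bundle: ReportBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    (out_dir / "stats.json").write_text(json.dumps(bundle.stats, indent=2))
    (out_dir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))


def _resolve_scenarios(sim: Dict) -> Dict:
    groups = sim.get("groups")
    if not groups:
        raise ConfigError("simulate section requires a 'groups' mapping")
    out = {}
    for name, scen in groups.items():
        if isinstance(scen, str):
            if scen not in SCENARIOS:
                raise ConfigError(f"unknown scenario preset {scen!r}")
            out[name] = scenario(scen)
        else:
            raise ConfigError("scenario entries must name a preset")
    return out


def _resolve_trajectories(config: RunConfig):
    """Returns (trajectories, group_of_fly, cohort-or-None)."""
    if config.simulate:
        sim = config.simulate
        cohort = generate_cohort(
            _resolve_scenarios(sim),
            n_per_group=int(sim.get("n_per_group", 8)),
            seed=config.seed,
            duration_s=float(sim.get("duration_s",
                                     config.protocol.total_duration_s)),
            arena=config.arena,
            protocol=config.protocol,
            with_spikes=bool(sim.get("with_spikes", False)),
            spike_duration_s=float(sim.get("spike_duration_s", 240.0)),
        )
        trajs = [r.labeled.trajectory for r in cohort.records]
        groups = {r.fly_id: r.group for r in cohort.records}
        return trajs, groups, cohort
    path = (config.inputs or {}).get("trajectories")
    if not path:
        raise ConfigError("inputs section requires a 'trajectories' path")
    trajs = load_trajectories(path, arena=config.arena,
                              fps=float(config.thresholds.get("fps", 30.0)))
    return trajs, {t.fly_id: "all" for t in trajs}, None


def run_behavior_analysis(config: RunConfig) -> ReportBundle:
    """Open-field pipeline: locomotion metrics, ethograms, immobilization,
    cohort onset curves and group statistics."""
    th = config.thresholds
    trajs, groups, _ = _resolve_trajectories(config)
    intervals = config.protocol.analysis_intervals

    loco_rows = []
    for traj in trajs:
        for iv in intervals:
            s = locomotion_summary(
                traj, iv, config.arena,
                active_speed_threshold=float(th.get("active_speed_threshold", 1.0)),
                smoothing_frames=int(th.get("smoothing_frames", 5)),
                k_sd=float(th.get("k_sd", 10.0)),
                debounce_frames=int(th.get("debounce_frames", 10)),
            )
            loco_rows.append({"group": groups[traj.fly_id], **s.__dict__})
    loco = pd.DataFrame(loco_rows)

    model_path = config.classifier.get("model")
    if model_path:
        model, fm = load_model(model_path)
    elif "train" in config.classifier or config.simulate:
        tr = config.classifier.get("train", {}) or {}
        model, fm = train_behavior_classifier(
            trajs,
            window_s=float(tr.get("window_s", 2.0)),
            n_components=int(tr.get("n_components", 5)),
            seed=config.seed,
            n_restarts=int(tr.get("n_restarts", 5)),
        )
    else:
        raise ConfigError("classification requested but no classifier model "
                          "or training request in config")

    min_bout_s = float(th.get("min_bout_s", 2.0))
    etho_rows, imm_rows = [], []
    onset_by_group: Dict[str, List] = {}
    for traj in trajs:
        seq = decode_states(model, traj, fm)
        etho_rows.append(pd.DataFrame({
            "fly_id": seq.fly_id,
            "frame": np.arange(len(seq)),
            "time_s": seq.time_s,
            "label": seq.labels,
            "confidence": seq.confidence,
        }))
        for iv in intervals:
            summ = immobilization_summary(seq, iv, min_bout_s=min_bout_s)
            imm_rows.append({"group": groups[traj.fly_id], **summ.__dict__})
            if iv.name == "high_temp":
                onset_by_group.setdefault(groups[traj.fly_id], []).append(summ)
    ethograms = pd.concat(etho_rows, ignore_index=True)
    imm = pd.DataFrame(imm_rows)

    onset_rows = []
    try:
        ht = config.protocol.interval("high_temp")
        for g, summs in onset_by_group.items():
            t, frac = cumulative_onset_curve(summs, ht)
            onset_rows.append(pd.DataFrame({"group": g, "time_s": t,
                                            "cumulative_fraction": frac}))
    except KeyError:
        pass
    onset = (pd.concat(onset_rows, ignore_index=True)
             if onset_rows else pd.DataFrame())

    stats_out: Dict = {}
    ht_imm = imm[imm["interval"] == "high_temp"] if "interval" in imm else imm
    by_group = {g: d["total_immobilized_s"].to_numpy()
                for g, d in ht_imm.groupby("group")}
    if len(by_group) >= 2 and all(len(v) >= 2 for v in by_group.values()):
        rep = kruskal_wallis_posthoc(GroupedMeasurements(
            by_group, metric="total_immobilized_s", units="s"))
        stats_out["immobilization_high_temp"] = {
            "omnibus_H": rep.omnibus_statistic,
            "omnibus_p": rep.omnibus_p,
            "pairwise": [pw.__dict__ for pw in rep.pairwise],
        }

    bundle = ReportBundle(
        tables={"locomotion": loco, "immobilization": imm,
                "ethograms": ethograms, "onset_curves": onset},
        stats=stats_out,
        manifest=_manifest(config, "behavior"),
    )
    _write(bundle, config.out_dir)
    save_model(config.out_dir / "model.json", model, fm)
    return bundle


def run_ephys_analysis(config: RunConfig) -> ReportBundle:
    """Tethered-fly pipeline: overall firing frequency over the standard
    240-s window, burst counts/rates, bilateral synchrony and phase-plot
    exports."""
    th = config.thresholds
    region = BurstRegion(**(th.get("burst_region") or {}))
    rec_s = float(th.get("recording_s", 240.0))

    trains_by_fly: Dict[str, Dict] = {}
    groups: Dict[str, str] = {}
    if config.simulate:
        sim = config.simulate
        scens = _resolve_scenarios(sim)
        n = int(sim.get("n_per_group", 8))
        from .synthetic import _child_seed, generate_spike_train
        idx = 0
        for g, scen in scens.items():
            for j in range(n):
                fid = f"{g}_{j:03d}"
                trains, _ = generate_spike_train(scen, rec_s,
                                                 _child_seed(config.seed, idx))
                idx += 1
                trains_by_fly[fid] = trains
                groups[fid] = g
    else:
        path = (config.inputs or {}).get("spikes")
        if not path:
            raise ConfigError("ephys run requires simulate groups or an "
                              "inputs.spikes path")
        trains_by_fly["fly_000"] = read_spike_trains(path, t0=0.0, t1=rec_s)
        groups["fly_000"] = "all"

    rows, burst_rows, phase_rows = [], [], []
    for fid, trains in trains_by_fly.items():
        sets = {}
        for ch, tr in trains.items():
            phase = cv2_series(tr)
            bs = count_bursts(phase, tr, region)
            sets[ch] = bs
            rows.append({
                "fly_id": fid, "group": groups[fid], "channel": ch,
                "overall_freq_hz": overall_firing_frequency(tr, (0.0, rec_s)),
                "burst_count": bs.count,
                "burst_rate_per_min": bs.count / (rec_s / 60.0),
                "synchrony_method": "overlap-fraction",
            })
            for b in bs.bursts:
                burst_rows.append({"fly_id": fid, "channel": ch, **b.__dict__})
            phase_rows.append(pd.DataFrame({
                "fly_id": fid, "channel": ch,
                "isi_freq_hz": phase.isi_freq, "cv2": phase.cv2,
            }))
        chans = list(sets)
        sync = (burst_synchrony(sets[chans[0]], sets[chans[1]],
                                tolerance_s=float(th.get("sync_tolerance_s", 1.0)))
                if len(chans) == 2 else None)
        for r in rows:
            if r["fly_id"] == fid:
                r["synchrony"] = sync if sync is not None else float("nan")
    report = pd.DataFrame(rows)
    bursts = pd.DataFrame(burst_rows)
    phases = (pd.concat(phase_rows, ignore_index=True)
              if phase_rows else pd.DataFrame())

    stats_out: Dict = {}
    by_group = {g: d["overall_freq_hz"].to_numpy()
                for g, d in report.groupby("group")}
    if len(by_group) >= 2 and all(len(v) >= 2 for v in by_group.values()):
        rep = kruskal_wallis_posthoc(GroupedMeasurements(
            by_group, metric="overall_freq_hz", units="Hz"))
        stats_out["overall_frequency"] = {
            "omnibus_H": rep.omnibus_statistic,
            "omnibus_p": rep.omnibus_p,
            "pairwise": [pw.__dict__ for pw in rep.pairwise],
        }

    bundle = ReportBundle(
        tables={"ephys": report, "bursts": bursts, "phase_trajectories": phases},
        stats=stats_out,
        manifest=_manifest(config, "ephys"),
    )
    _write(bundle, config.out_dir)
    return bundle
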