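"""Run configuration: a single structured-text (YAML) file drives a run.

All thresholds default to the module defaults and are overridable here; the
master seed is recorded in every output artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .arena import AnalysisInterval, ArenaSpec, Phase, ProtocolSchedule

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 0
    out_dir: Path = Path("runs/out")
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    protocol: ProtocolSchedule = field(default_factory=ProtocolSchedule.default)
    simulate: Optional[Dict[str, Any]] = None   # groups, n_per_group, duration_s, ...
    inputs: Optional[Dict[str, Any]] = None     # trajectories / spikes paths
    classifier: Dict[str, Any] = field(default_factory=dict)
    thresholds: Dict[str, Any] = field(default_factory=dict)
    raw: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.simulate is None and self.inputs is None:
            raise ConfigError("config must provide either 'simulate' or 'inputs'")
        if self.inputs:
            for key, p in self.inputs.items():
                if p and not Path(p).exists():
                    raise ConfigError(f"input path for {key!r} does not exist: {p}")
        model_path = self.classifier.get("model")
        if model_path and not Path(model_path).exists():
            raise ConfigError(f"classifier model not found: {model_path}")

    def config_hash(self) -> str:
        # output location is not part of the scientific configuration
        doc = {k: v for k, v in self.raw.items() if k != "out_dir"}
        doc["seed"] = self.seed
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _parse_arena(doc: Dict[str, Any]) -> ArenaSpec:
    try:
        return ArenaSpec(**doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid arena spec: {exc}") from exc


def _parse_protocol(doc) -> ProtocolSchedule:
    if doc in (None, "default"):
        return ProtocolSchedule.default()
    try:
        phases = tuple(
            Phase(p["name"], float(p["start_s"]), float(p["end_s"]),
                  tuple(p.get("temperature_C", (21.0, 21.0))))
            for p in doc["phases"]
        )
        intervals = tuple(
            AnalysisInterval(i["name"], float(i["start_s"]), float(i["end_s"]))
            for i in doc["analysis_intervals"]
        )
        return ProtocolSchedule(phases, intervals)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid protocol: {exc}") from exc


def load_config(path, seed: Optional[int] = None,
                out_dir: Optional[str] = None) -> RunConfig:
    """Parse a YAML run configuration; CLI flags may override seed/out_dir."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    return RunConfig(
        seed=int(seed if seed is not None else doc.get("seed", 0)),
        out_dir=Path(out_dir or doc.get("out_dir", "runs/out")),
        arena=_parse_arena(doc.get("arena", {})),
        protocol=_parse_protocol(doc.get("protocol")),
        simulate=doc.get("simulate"),
        inputs=doc.get("inputs"),
        classifier=doc.get("classifier", {}),
        thresholds=doc.get("thresholds", {}),
        raw=doc,
    )
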