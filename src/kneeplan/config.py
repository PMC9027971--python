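"""YAML run configuration: model, training, blueprint constants, registry.

A single structured file configures a run; every section is optional and
falls back to package defaults. The loaded dictionary is also hashed so a
run's provenance (seed + config) can be logged.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .model import ModelConfig, TaskKind, TaskSpec, Topology
from .planning import Application, PlanBlueprint
from .training import OptimizerKind, TrainConfig, WeightingKind

DEFAULT_TASKS = (
    TaskSpec(name="bones", kind=TaskKind.segmentation, n_channels=2, channel_labels=("S1", "S2")),
    TaskSpec(
        name="keypoints",
        kind=TaskKind.keypoint,
        n_channels=7,
        channel_labels=("K1", "K2", "K3", "K4", "K5", "K6", "K7"),
    ),
    TaskSpec(name="lines", kind=TaskKind.line, n_channels=3, channel_labels=("L1", "L2", "L3")),
)


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def tasks_from_config(cfg: dict) -> tuple[TaskSpec, ...]:
    entries = cfg.get("tasks")
    if not entries:
        return DEFAULT_TASKS
    return tuple(
        TaskSpec(
            name=e["name"],
            kind=TaskKind(e["kind"]),
            n_channels=int(e["n_channels"]),
            channel_labels=tuple(e.get("channel_labels", ())),
        )
        for e in entries
    )


def model_config_from(cfg: dict, **overrides) -> ModelConfig:
    section = dict(cfg.get("model", {}))
    section.update(overrides)
    return ModelConfig(
        tasks=tasks_from_config(cfg),
        topology=Topology(section.get("topology", "multi_head")),
        n_features=int(section.get("n_features", 128)),
        depth=int(section.get("depth", 4)),
        input_size=int(section.get("input_size", 256)),
        seed=int(section.get("seed", 0)),
    )


def train_config_from(cfg: dict, **overrides) -> TrainConfig:
    section = dict(cfg.get("training", {}))
    section.update(overrides)
    kwargs = {}
    for f in TrainConfig.__dataclass_fields__:
        if f in section:
            kwargs[f] = section[f]
    if "optimizer" in kwargs:
        kwargs["optimizer"] = OptimizerKind(kwargs["optimizer"])
    if "weighting" in kwargs:
        kwargs["weighting"] = WeightingKind(kwargs["weighting"])
    return TrainConfig(**kwargs)


def blueprint_from(cfg: dict, application) -> PlanBlueprint:
    app = Application(application)
    section = cfg.get("blueprints", {}).get(app.value, {})
    return PlanBlueprint(
        application=app,
        constants=dict(section.get("constants", {})),
        roles=dict(section.get("roles", {})),
    )
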