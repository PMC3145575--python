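"""Run configuration (YAML or JSON)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import IO

import yaml

from .ilp import ObjectiveWeights
from .normalization import NormalizationParams

__all__ = ["PoolSettings", "RunConfig", "load_config"]


@dataclass
class PoolSettings:
    tolerance: float = 0.10
    max_solutions: int = 100


@dataclass
class RunConfig:
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    objective: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    pool: PoolSettings = field(default_factory=PoolSettings)
    backend: str = "highs"
    seed: int = 0
    inhibitor_mode: str = "block-activity"
    allow_cycles: bool = False
    retain_fraction: float = 0.6
    ridge: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(stream: IO | str | dict) -> RunConfig:
    if isinstance(stream, dict):
        raw = stream
    elif isinstance(stream, str):
        raw = yaml.safe_load(stream)
    else:
        raw = yaml.safe_load(stream.read())
    raw = raw or {}
    cfg = RunConfig()
    if "normalization" in raw:
        cfg.normalization = NormalizationParams(**raw["normalization"])
    if "objective" in raw:
        cfg.objective = ObjectiveWeights(**raw["objective"])
    if "pool" in raw:
        cfg.pool = PoolSettings(**raw["pool"])
    for key in ("backend", "seed", "inhibitor_mode", "allow_cycles", "retain_fraction", "ridge"):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg


def dump_config(cfg: RunConfig, stream: IO) -> None:
    json.dump(cfg.to_dict(), stream, indent=1, sort_keys=True, default=str)
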