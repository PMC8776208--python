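"""Run configuration: one YAML-loadable object covering every stage.

All stage parameters carry the module defaults; unknown keys are rejected so
a typo cannot silently fall back to a default.  A single integer seed drives
every source of randomness (the synthetic generator derives per-participant
substreams from it), so a config fully determines a run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synthetic import SimConfig


@dataclass(frozen=True)
class RunConfig:
    # hrv_nightly
    neighborhood: int = 5
    rel_threshold: float = 0.30
    segment_minutes: int = 5
    min_valid_fraction: float = 0.5
    min_normal_ibis: int = 30
    # daily_features
    window_days: int = 7
    min_obs: int = 3
    include_current: bool = False
    # trend_windows
    min_trend_obs: int = 10
    # questionnaire / association_models
    floor_threshold: float = 0.8
    outcomes: tuple[str, ...] = ("stress", "anxiety", "depression", "somatisation")
    force_outcomes: tuple[str, ...] = ()
    cluster_robust: bool = False
    make_plots: bool = True
    # synthetic_data
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        # the run seed supersedes any seed in the sim block
        if self.sim.seed != self.seed:
            object.__setattr__(self, "sim", SimConfig.from_dict({**self.sim.to_dict(), "seed": self.seed}))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(dict(d["sim"]))
        for k in ("outcomes", "force_outcomes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["outcomes"] = list(self.outcomes)
        d["force_outcomes"] = list(self.force_outcomes)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
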