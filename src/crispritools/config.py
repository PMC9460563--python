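"""Run configuration: a YAML file with one block per pipeline stage.

Unknown keys are rejected (both at the top level and inside stage
blocks), and every stochastic stage receives an explicit seed derived
from the global seed, so a config file fully determines a run.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import yaml

from .assay import AssayParams
from .metrics import MetricsParams
from .segmentation import SegmentationParams
from .simulate import BulkSimConfig, ColonySimConfig, CultureSimConfig
from .tracking import LinkingParams

__all__ = ["RunConfig", "load_config", "derive_seed"]

_STAGE_TYPES = {
    "colony": ColonySimConfig,
    "plate": BulkSimConfig,
    "culture": CultureSimConfig,
    "segmentation": SegmentationParams,
    "tracking": LinkingParams,
    "metrics": MetricsParams,
    "assay": AssayParams,
}

_STAGE_ORDER = tuple(_STAGE_TYPES)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    idx = _STAGE_ORDER.index(stage)
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


class RunConfig:
    """Validated pipeline configuration."""

    def __init__(self, seed: int = 0, verbosity: int = 1, paths=None, **stages):
        self.seed = int(seed)
        self.verbosity = int(verbosity)
        self.paths = dict(paths or {})
        unknown = set(stages) - set(_STAGE_TYPES)
        if unknown:
            raise ValueError(f"unknown configuration block(s): {sorted(unknown)}")
        self.stages = {}
        for name, block in stages.items():
            cls = _STAGE_TYPES[name]
            block = dict(block or {})
            fields = {f.name for f in dataclasses.fields(cls)}
            bad = set(block) - fields
            if bad:
                raise ValueError(
                    f"unknown key(s) in {name!r} block: {sorted(bad)}"
                )
            if "seed" in fields and "seed" not in block:
                block["seed"] = derive_seed(self.seed, name)
            if "bootstrap_seed" in fields and "bootstrap_seed" not in block:
                block["bootstrap_seed"] = derive_seed(self.seed, name)
            self.stages[name] = cls(**block)

    def get(self, stage: str):
        """Stage parameters, defaulting (with derived seed) when absent."""
        if stage not in self.stages:
            return RunConfig(seed=self.seed, **{stage: {}}).stages[stage]
        return self.stages[stage]

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "verbosity": self.verbosity, "paths": self.paths}
        for name, params in self.stages.items():
            out[name] = dataclasses.asdict(params)
        return out


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration file must be a mapping")
    return RunConfig(**raw)
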