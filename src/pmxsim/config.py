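"""Declarative run configuration (YAML).

A run configuration bundles the solver block, a structural model (registry id
plus parameter map), dose regimens, and optionally a population, trial,
sweep or fit block, together with the master seed.  Configs are plain
key-value documents so they can be diffed, versioned and round-tripped;
``load_config`` -> ``dump_config`` -> ``load_config`` is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import DoseRegimen, SolverConfig
from .evaluation import SweepSpec
from .models import MODEL_BUILDERS, Model, build_model

__all__ = ["RunConfig", "load_config", "dump_config"]

_KNOWN_BLOCKS = {"solver", "model", "regimens", "population", "trial",
                 "sweep", "fit", "seed", "outputs", "log_level"}


@dataclass
class RunConfig:
    """Parsed configuration; blocks stay as plain mappings and are converted
    to domain objects on demand."""

    data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.data) - _KNOWN_BLOCKS
        if unknown:
            raise ValueError(f"unknown config block(s): {sorted(unknown)}")
        model = self.data.get("model")
        if model is not None and model.get("id") not in MODEL_BUILDERS:
            raise ValueError(
                f"unknown model id {model.get('id')!r}; "
                f"available: {sorted(MODEL_BUILDERS)}")

    @property
    def seed(self):
        return self.data.get("seed")

    def solver_config(self) -> SolverConfig:
        return SolverConfig(**self.data.get("solver", {}))

    def build_model(self) -> Model:
        block = self.data.get("model")
        if block is None:
            raise ValueError("config has no model block")
        return build_model(block["id"], **block.get("params", {}))

    def regimens(self) -> list[DoseRegimen]:
        return [DoseRegimen(**block) for block in self.data.get("regimens", [])]

    def sweep_spec(self) -> SweepSpec:
        block = self.data.get("sweep")
        if block is None:
            raise ValueError("config has no sweep block")
        block = dict(block)
        block["outputs"] = tuple(block.get("outputs", ()))
        return SweepSpec(**block)

    def trial_block(self) -> dict:
        block = self.data.get("trial")
        if block is None:
            raise ValueError("config has no trial block")
        return dict(block)

    def to_dict(self) -> dict:
        return dict(self.data)


def load_config(path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig(data)


def dump_config(config: RunConfig, path) -> None:
    """Serialize a configuration back to YAML (stable key order)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
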