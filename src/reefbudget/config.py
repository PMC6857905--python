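"""Run configuration: every named constant of the pipeline in one YAML schema.

The schema is strict (unknown keys are rejected) and fully serialisable, so a
sensitivity analysis is a one-line config edit and every output can embed a
hash of the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .acanthaster import AcanthasterParams
from .threshold import ThresholdModelSpec

__all__ = ["RunConfig", "load_config", "config_hash"]


class PathsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    benthic: str = "benthic.csv"
    mobile: str = "mobile.csv"
    fish: str = "fish.csv"
    traits: str | None = None  # None -> packaged default table
    out_dir: str = "out"


class ConstantsConfig(BaseModel):
    """Named constants of the production and erosion equations."""

    model_config = ConfigDict(extra="forbid")

    sedimentation_rate: float = 0.4
    ca_rate: float = 0.018
    unit_scale: float = 10.0
    reeftime: float = 9.0
    mec: float = 10.0
    default_brc: float = 20.0
    accretion_alpha: float = -0.01949
    accretion_basis: str = Field(default="net_with_acanthaster", pattern="^net(_with_acanthaster)?$")
    urchin_belt_m2: float = Field(default=6.0, gt=0)
    acanthaster_belt_m2: float = Field(default=50.0, gt=0)
    fish_transect_m2: float = Field(default=120.0, gt=0)


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    rise_rate: float = Field(ge=0)


_DEFAULT_SCENARIOS = [
    ScenarioConfig(name="RCP2.6", rise_rate=5.0),
    ScenarioConfig(name="RCP4.5", rise_rate=6.5),
    ScenarioConfig(name="RCP6.0", rise_rate=6.7),
    ScenarioConfig(name="RCP8.5", rise_rate=9.0),
]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    paths: PathsConfig = Field(default_factory=PathsConfig)
    constants: ConstantsConfig = Field(default_factory=ConstantsConfig)
    acanthaster: AcanthasterParams = Field(default_factory=AcanthasterParams)
    model: ThresholdModelSpec = Field(default_factory=ThresholdModelSpec)
    scenarios: list[ScenarioConfig] = Field(
        default_factory=lambda: list(_DEFAULT_SCENARIOS)
    )
    seed: int = 0
    verbosity: int = Field(default=1, ge=0, le=2)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a strict YAML run configuration; None yields all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the full configuration, for output provenance."""
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
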