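"""Run configuration: YAML-backed, schema-validated, unknown keys rejected."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FingerprintConfig(_Strict):
    radius: int = 2
    nbits: int = 2048


class PropertyConfig(_Strict):
    """One property: its data/model source, desirability, and weights."""

    name: str
    data: Optional[str] = None        # CSV (smiles,value) for training
    model_path: Optional[str] = None  # persisted model directory
    units: str = ""
    shape: Literal["gaussian", "max_gaussian", "min_gaussian"] = "max_gaussian"
    mu: float = 0.0
    sigma_v: float = 1.0
    weight: float = Field(default=1.0, ge=0.0)
    scaler_sigma: float = Field(default=0.25, gt=0.0)  # DSS Scaler strictness

    @model_validator(mode="after")
    def _source_given(self):
        if self.data is None and self.model_path is None:
            raise ValueError(f"property {self.name!r} needs either data or model_path")
        return self


class DSSBlock(_Strict):
    top_fraction: float = Field(default=0.10, gt=0.0, le=1.0)
    valid_only: bool = False


class SpaceBlock(_Strict):
    lo: float = 0.1
    hi: float = 0.9
    step: float = 0.01
    grids: Optional[list[list[float]]] = None  # explicit per-property grids


class GeneratorBlock(_Strict):
    corpus: Optional[str] = None  # .smi file for the token policy
    order: int = Field(default=3, ge=0)
    budget: int = Field(default=10_000, ge=1)
    ucb_c: float = 1.0
    max_tokens: int = Field(default=80, ge=1)


class EpisodeBlock(_Strict):
    n_random: int = Field(default=10, ge=1)
    n_bo: int = Field(default=30, ge=0)
    n_episodes: int = Field(default=5, ge=1)


class RunConfig(_Strict):
    properties: list[PropertyConfig]
    fingerprint: FingerprintConfig = FingerprintConfig()
    dss: DSSBlock = DSSBlock()
    space: SpaceBlock = SpaceBlock()
    generator: GeneratorBlock = GeneratorBlock()
    episode: EpisodeBlock = EpisodeBlock()
    seed: int = 0

    @model_validator(mode="after")
    def _some_weight(self):
        if self.properties and not any(p.weight > 0 for p in self.properties):
            raise ValueError("at least one property weight must be positive")
        return self


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must hold a mapping")
    return RunConfig.model_validate(data)
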