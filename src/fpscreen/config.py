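"""Validated pipeline configuration, round-trippable through YAML.

A single master seed drives everything: per-spectrum noise seeds, the
validation split, the fold plan and classifier initialization are all
derived from it deterministically, so one integer reproduces a run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .classify import ALL_FAMILIES
from .exceptions import ConfigError

__all__ = ["SimulatorConfig", "PreprocessingConfig", "SplitConfig",
           "ClassifierConfig", "PipelineConfig", "load_config"]


class SimulatorConfig(BaseModel):
    cavity_length_um: float = 280.0
    center_wavelength_nm: float = 1550.0
    spectral_width_nm: float = 35.0
    visibility: float = 0.9956
    noise_sd: float = 0.01
    noise_correlation_nm: float = 0.5
    grid_min_nm: float = 1530.0
    grid_max_nm: float = 1570.0
    grid_points: int = 2001
    index_min: float = 1.30
    index_max: float = 1.50
    index_step: float = 0.01
    replicates: int = 10

    @model_validator(mode="after")
    def _check(self) -> "SimulatorConfig":
        if self.cavity_length_um <= 0:
            raise ValueError("cavity_length_um must be positive")
        if not 0.0 <= self.visibility <= 1.0:
            raise ValueError("visibility must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_correlation_nm < 0:
            raise ValueError("noise_correlation_nm must be non-negative")
        if self.grid_min_nm >= self.grid_max_nm:
            raise ValueError("grid_min_nm must be below grid_max_nm")
        if not self.grid_min_nm <= self.center_wavelength_nm <= self.grid_max_nm:
            raise ValueError("grid must cover the center wavelength")
        if self.grid_points < 3:
            raise ValueError("grid_points must be >= 3")
        if self.spectral_width_nm <= 0:
            raise ValueError("spectral_width_nm must be positive")
        if not (1.0 < self.index_min <= self.index_max):
            raise ValueError("refractive indices must exceed 1 and be ordered")
        if self.index_step <= 0:
            raise ValueError("index_step must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        return self

    def label_indices(self) -> tuple[float, ...]:
        n = int(round((self.index_max - self.index_min) / self.index_step)) + 1
        return tuple(np.round(self.index_min + self.index_step * np.arange(n), 6))


class PreprocessingConfig(BaseModel):
    threshold: float = 0.05

    @field_validator("threshold")
    @classmethod
    def _check_threshold(cls, v: float) -> float:
        if not 0.0 <= v < 1.0:
            raise ValueError("threshold must be in [0, 1)")
        return v


class SplitConfig(BaseModel):
    k: int = 3
    validation_fraction: float = 0.2
    group_aware: bool = False

    @model_validator(mode="after")
    def _check(self) -> "SplitConfig":
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        return self


class ClassifierConfig(BaseModel):
    family: str
    hyperparameters: dict = Field(default_factory=dict)

    @field_validator("family")
    @classmethod
    def _check_family(cls, v: str) -> str:
        if v not in ALL_FAMILIES:
            raise ValueError(f"unknown classifier family {v!r}")
        return v


class PipelineConfig(BaseModel):
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)
    preprocessing: PreprocessingConfig = Field(default_factory=PreprocessingConfig)
    split: SplitConfig = Field(default_factory=SplitConfig)
    classifiers: list[ClassifierConfig] = Field(
        default_factory=lambda: [ClassifierConfig(family=f) for f in ALL_FAMILIES]
    )
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        vals = ss.generate_state(3) % (2**31)
        return {
            "simulate": int(vals[0]),
            "split": int(vals[1]),
            "classify": int(vals[2]),
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file (or defaults) with keyword overrides."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is not None:
            if not isinstance(raw, dict):
                raise ConfigError(f"config file {path} must contain a mapping")
            data = raw
    data.update(overrides)
    try:
        return PipelineConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
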