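"""Validated run configurations for the three headline experiments.

A :class:`RunConfig` names one experiment — ``variant_profile`` (variant
effects across polygenic backgrounds and background rates),
``variance_scaling`` (PGS variance vs. number of contributing genes,
additive and epistatic), or ``environment_shift`` (three-phase selection
scenario) — together with every parameter the experiment needs and a root
seed.  Configs are YAML documents; unknown keys are rejected and every
parameter is validated against its domain with an error naming the key.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "RunConfig",
    "ProfileParams",
    "VarianceParams",
    "ScenarioParams",
    "ConfigError",
    "load_config",
    "dump_config",
]

ExperimentName = Literal["variant_profile", "variance_scaling", "environment_shift"]


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class ProfileParams(_StrictModel):
    """Variant-effect-profile experiment (log odds / odds / prevalence panels)."""

    background_rates: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1)
    delta: float = 1.0
    pgs_min: float = -4.0
    pgs_max: float = 4.0
    pgs_step: float = Field(default=0.1, gt=0)

    @field_validator("background_rates")
    @classmethod
    def _rates_in_open_unit(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if not v:
            raise ValueError("background_rates must be non-empty")
        for r in v:
            if not (0.0 < r < 1.0):
                raise ValueError(f"background_rate {r} outside (0, 1)")
        return v

    @model_validator(mode="after")
    def _grid_nonempty(self) -> "ProfileParams":
        if self.pgs_max < self.pgs_min:
            raise ValueError("pgs_max must be >= pgs_min")
        return self

    def grid(self) -> list[float]:
        import numpy as np

        n = int(round((self.pgs_max - self.pgs_min) / self.pgs_step)) + 1
        return list(np.linspace(self.pgs_min, self.pgs_max, n))


class VarianceParams(_StrictModel):
    """Variance-scaling experiment across gene counts."""

    gene_counts: tuple[int, ...] = (10, 50, 100, 500, 1000)
    n_individuals: int = Field(default=10_000, ge=1)
    n_replicates: int = Field(default=10, ge=2)
    freq_low: float = 0.05
    freq_high: float = 0.5
    effect_mean: float = 0.0
    effect_sd: float = Field(default=0.1, ge=0)
    interaction_density: float = Field(default=0.05, ge=0, le=1)
    interaction_mean: float = 0.0
    interaction_sd: float = Field(default=0.1, ge=0)
    modes: tuple[Literal["additive", "epistatic"], ...] = ("additive", "epistatic")
    resample_architectures: bool = True

    @field_validator("gene_counts")
    @classmethod
    def _counts_increasing(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        if not v or any(g < 1 for g in v) or list(v) != sorted(set(v)):
            raise ValueError("gene_counts must be strictly increasing positive integers")
        return v

    @model_validator(mode="after")
    def _freq_band(self) -> "VarianceParams":
        if not (0.0 < self.freq_low <= self.freq_high < 1.0):
            raise ValueError("require 0 < freq_low <= freq_high < 1")
        return self


class ScenarioParams(_StrictModel):
    """Three-phase environment-shift selection scenario."""

    n_genes: int = Field(default=100, ge=1)
    n_individuals: int = Field(default=5_000, ge=2)
    generations_per_phase: tuple[int, int, int] = (10, 50, 10)
    shift_offset: float = Field(default=2.0, ge=0)
    selection_strength: float = Field(default=0.5, gt=0, le=1)
    background_rate: float = 0.01
    freq_low: float = 0.05
    freq_high: float = 0.5
    effect_mean: float = 0.0
    effect_sd: float = Field(default=0.1, ge=0)
    selection_mode: Literal["soft", "hard"] = "soft"

    @field_validator("background_rate")
    @classmethod
    def _rate_open_unit(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError(f"background_rate {v} outside (0, 1)")
        return v

    @field_validator("generations_per_phase")
    @classmethod
    def _phases_positive(cls, v: tuple[int, int, int]) -> tuple[int, int, int]:
        if len(v) != 3 or any(g < 1 for g in v):
            raise ValueError("generations_per_phase must be three positive integers")
        return v

    @model_validator(mode="after")
    def _freq_band(self) -> "ScenarioParams":
        if not (0.0 < self.freq_low <= self.freq_high < 1.0):
            raise ValueError("require 0 < freq_low <= freq_high < 1")
        return self


class RunConfig(_StrictModel):
    """Complete, validated configuration for one experiment run."""

    experiment: ExperimentName
    root_seed: int = Field(default=0, ge=0)
    profile: ProfileParams = ProfileParams()
    variance: VarianceParams = VarianceParams()
    scenario: ScenarioParams = ScenarioParams()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys are filled with documented defaults; unknown keys and
    out-of-domain values raise :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not valid YAML: {exc}") from exc
    if doc is None:
        raise ConfigError(f"config file {path} is empty")
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {path} must be a mapping at top level")
    try:
        return RunConfig.model_validate(doc)
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc


def dump_config(config: RunConfig) -> str:
    """Serialize a config to YAML; load_config of the result round-trips."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
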