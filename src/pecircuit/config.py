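"""Run configuration: YAML-backed, schema-validated."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .stimuli import PRESETS, StimulusProtocol, get_preset
from .circuit import PerturbationSpec

__all__ = ["RunConfig", "ProtocolConfig", "PerturbationConfig", "load_config",
           "ConfigError"]


class ConfigError(ValueError):
    """Malformed, unparseable or schema-violating configuration."""


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    preset: Optional[str] = None
    n_trials: Optional[int] = Field(None, ge=1)
    n_values: Optional[int] = Field(None, ge=1)
    steps_per_value: Optional[int] = Field(None, ge=1)
    mu_trial: Optional[float] = None
    sigma2_trial: Optional[float] = Field(None, ge=0)
    trial_mean: Optional[float | tuple[float, float]] = None
    sigma2_in: Optional[float] = Field(None, ge=0)
    family: Literal["normal", "uniform"] = "normal"
    scalar_variability: Optional[float] = Field(None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "ProtocolConfig":
        if self.preset is None:
            required = ("n_trials", "n_values", "steps_per_value")
            missing = [k for k in required if getattr(self, k) is None]
            if missing:
                raise ValueError(f"inline protocol missing keys: {missing}")
            if self.trial_mean is None and self.mu_trial is None:
                raise ValueError("inline protocol needs trial_mean or "
                                 "mu_trial/sigma2_trial")
        elif self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        return self

    def build(self) -> StimulusProtocol:
        if self.preset is not None:
            overrides = {k: v for k, v in dict(
                n_trials=self.n_trials, n_values=self.n_values,
                steps_per_value=self.steps_per_value,
                sigma2_in=self.sigma2_in,
            ).items() if v is not None}
            return get_preset(self.preset, **overrides)
        if self.trial_mean is not None:
            tm = self.trial_mean
            if isinstance(tm, (list, tuple)):
                tm = (float(tm[0]), float(tm[1]))
            return StimulusProtocol(
                self.n_trials, self.n_values, self.steps_per_value, tm,
                sigma2_in=self.sigma2_in or 0.0, family=self.family,
                scalar_variability=self.scalar_variability)
        return StimulusProtocol.from_variances(
            self.n_trials, self.n_values, self.steps_per_value,
            mu_trial=self.mu_trial, sigma2_trial=self.sigma2_trial or 0.0,
            sigma2_in=self.sigma2_in or 0.0, family=self.family,
            scalar_variability=self.scalar_variability)


class PerturbationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    targets: dict[Literal["PV", "SOM", "VIP"], float]
    scope: Literal["lower", "higher", "both"] = "both"
    onset_trial: int = Field(0, ge=0)

    def build(self) -> PerturbationSpec:
        return PerturbationSpec(targets=dict(self.targets), scope=self.scope,
                                onset_trial=self.onset_trial)


class RunConfig(BaseModel):
    """Fully concrete description of one simulation run."""

    model_config = ConfigDict(extra="forbid")

    variant: Literal["MFN1", "MFN2", "MFN3"] = "MFN1"
    lambda_low: float = Field(4.5e-2, gt=0)
    lambda_high: float = Field(7e-4, gt=0)
    protocol: ProtocolConfig
    perturbation: Optional[PerturbationConfig] = None
    dt: float = Field(1.0, gt=0)
    seed: int = 0
    outdir: str = "results"
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Errors name the offending key; unknown keys are rejected.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raise ConfigError(f"empty configuration file: {path}")
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
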