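"""Scenario configuration: one validated document describing a dosing study.

Defaults reproduce the nominal experiment (sulfathiazole rates, T = 6 h,
+/-10% uncertainty, target 50 mg/mL, 144 h horizon).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .core_model import NOMINAL_RATES_H, RateConstants

__all__ = ["Scenario", "RatesConfig", "load_scenario"]


class RatesConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ka: float = NOMINAL_RATES_H["ka"]
    ke1: float = NOMINAL_RATES_H["ke1"]
    k23: float = NOMINAL_RATES_H["k23"]
    ke3: float = NOMINAL_RATES_H["ke3"]

    @field_validator("ka", "ke1", "k23", "ke3")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"rate must be strictly positive: {info.field_name}={v}")
        return v

    def to_rate_constants(self) -> RateConstants:
        return RateConstants(self.ka, self.ke1, self.k23, self.ke3)


class TherapeuticRangeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lower: float
    upper: float

    @field_validator("upper")
    @classmethod
    def _ordered(cls, v: float, info) -> float:
        if "lower" in info.data and v <= info.data["lower"]:
            raise ValueError("therapeutic range requires lower < upper")
        return v


class ControllerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ki: float = Field(default=0.1, gt=0)
    loading_dose: float | None = None
    scale_factor: float | None = Field(default=None, gt=0)
    scale_first: int = Field(default=0, ge=0)


class FeedbackConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    destab_entry: float = 0.7
    destab_row: int = 0
    destab_col: int = 0
    eps_plus: float = Field(default=1e-3, gt=0)
    eps_minus: float = Field(default=-1e-3, lt=0)
    alpha: float = Field(default=1.01, gt=1)
    v: list[float] = Field(default_factory=lambda: [1.0, 1.0, 1.0])


class Scenario(BaseModel):
    """Fully validated dosing scenario; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    rates: RatesConfig = Field(default_factory=RatesConfig)
    T_hours: float = Field(default=6.0, gt=0)
    delta: float = Field(default=0.1, ge=0)
    target: float = Field(default=50.0, ge=0)
    horizon_h: float = Field(default=144.0, gt=0)
    controller: ControllerConfig = Field(default_factory=ControllerConfig)
    feedback: FeedbackConfig = Field(default_factory=FeedbackConfig)
    therapeutic_range: TherapeuticRangeConfig | None = None

    @field_validator("delta")
    @classmethod
    def _delta_bound(cls, v: float) -> float:
        if v >= 1.0:
            raise ValueError(
                f"delta={v} rejected: would permit negative parameters"
            )
        return v

    @property
    def horizon_steps(self) -> int:
        return int(round(self.horizon_h / self.T_hours))

    def rate_constants(self) -> RateConstants:
        return self.rates.to_rate_constants()


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    if payload is None:
        raise ValueError(f"scenario file {path} is empty")
    if not isinstance(payload, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    return Scenario.model_validate(payload)
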