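"""Generator and pipeline configuration models."""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Dict, Tuple

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

__all__ = [
    "ConfigurationError",
    "PersistenceModel",
    "DemographicsModel",
    "DxModel",
    "LognormalParams",
    "GeneratorConfig",
    "load_config",
]


class ConfigurationError(ValueError):
    """Raised when a generator configuration is invalid; names the offending field."""


class PersistenceModel(BaseModel):
    """Per-patient two-state refill process.

    At each supply exhaustion the patient refills immediately with
    probability ``refill_prob`` (drawn per patient around
    ``refill_prob_mean``).  Otherwise, with probability
    ``gap_restart_prob`` a geometric gap of mean ``gap_mean_days`` passes
    before the next fill; with the remaining probability the drug is
    discontinued for good.
    """

    refill_prob_mean: float = 0.78
    refill_prob_sd: float = 0.10
    gap_restart_prob: float = 0.25
    gap_mean_days: float = 21.0
    days_supply: int = 30

    @model_validator(mode="after")
    def _check(self) -> "PersistenceModel":
        for name in ("refill_prob_mean", "refill_prob_sd", "gap_restart_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"persistence_model.{name} must be in [0, 1]")
        if self.gap_mean_days < 1.0:
            raise ValueError("persistence_model.gap_mean_days must be >= 1")
        if self.days_supply < 1:
            raise ValueError("persistence_model.days_supply must be >= 1")
        return self


class DemographicsModel(BaseModel):
    age_min: int = 18
    age_max: int = 63
    ineligible_age_prob: float = 0.03
    sex_probs: Dict[str, float] = Field(default_factory=lambda: {"M": 0.57, "F": 0.43})
    race_probs: Dict[str, float] = Field(
        default_factory=lambda: {
            "Black": 0.361,
            "White": 0.318,
            "Hispanic": 0.097,
            "Other": 0.018,
            "Unknown": 0.206,
        }
    )

    @model_validator(mode="after")
    def _check(self) -> "DemographicsModel":
        if self.age_min > self.age_max:
            raise ValueError("demographics.age_min must be <= age_max")
        for name in ("sex_probs", "race_probs"):
            probs = getattr(self, name)
            if any(not 0.0 <= p <= 1.0 for p in probs.values()):
                raise ValueError(f"demographics.{name} entries must be in [0, 1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"demographics.{name} must sum to 1")
        if not 0.0 <= self.ineligible_age_prob <= 1.0:
            raise ValueError("demographics.ineligible_age_prob must be in [0, 1]")
        return self


class DxModel(BaseModel):
    """Diagnosis-coding behaviour of the synthetic claim stream."""

    f20_outpatient_prob: float = 0.20
    f20_ed_prob: float = 0.25
    f20_inpatient_prob: float = 0.60
    evidence_missing_prob: float = 0.04
    bipolar_prob: float = 0.39
    mdd_prob: float = 0.27
    schizoaffective_prob: float = 0.40
    charlson_prob: float = 0.30

    @model_validator(mode="after")
    def _check(self) -> "DxModel":
        for name, v in self.model_dump().items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"dx_model.{name} must be in [0, 1]")
        return self


class LognormalParams(BaseModel):
    mu: float
    sigma: float

    @field_validator("sigma")
    @classmethod
    def _sigma_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("cost_params sigma must be >= 0")
        return v


def _default_costs() -> Dict[str, LognormalParams]:
    return {
        "inpatient": LognormalParams(mu=8.6, sigma=1.0),
        "ed": LognormalParams(mu=5.9, sigma=1.0),
        "outpatient": LognormalParams(mu=4.6, sigma=1.1),
        "pharmacy": LognormalParams(mu=4.2, sigma=1.0),
    }


def _default_drug_mix() -> Dict[str, float]:
    return {
        "quetiapine": 0.256,
        "risperidone": 0.248,
        "olanzapine": 0.197,
        "aripiprazole": 0.137,
        "lurasidone": 0.051,
        "ziprasidone": 0.043,
        "paliperidone": 0.030,
        "clozapine": 0.038,
    }


class GeneratorConfig(BaseModel):
    """Full parameterization of the synthetic claims generator."""

    n_patients: int
    seed: int = 0
    index_window: Tuple[dt.date, dt.date] = (dt.date(2016, 7, 1), dt.date(2019, 12, 31))
    drug_mix: Dict[str, float] = Field(default_factory=_default_drug_mix)
    persistence_model: PersistenceModel = Field(default_factory=PersistenceModel)
    switch_prob: float = 0.16
    augment_prob: float = 0.032
    lai_prob: float = 0.10
    typical_ap_baseline_prob: float = 0.04
    dual_eligible_prob: float = 0.03
    enrollment_gap_prob: float = 0.03
    hosp_rate: float = 0.6
    hosp_los_mean: float = 8.0
    ed_rate: float = 3.0
    outpatient_rate: float = 25.0
    cost_params: Dict[str, LognormalParams] = Field(default_factory=_default_costs)
    demographics: DemographicsModel = Field(default_factory=DemographicsModel)
    dx_model: DxModel = Field(default_factory=DxModel)

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.index_window[0] >= self.index_window[1]:
            raise ValueError("index_window start must precede end")
        if not self.drug_mix:
            raise ValueError("drug_mix must be non-empty")
        if any(not 0.0 <= p <= 1.0 for p in self.drug_mix.values()):
            raise ValueError("drug_mix probabilities must be in [0, 1]")
        if abs(sum(self.drug_mix.values()) - 1.0) > 1e-9:
            raise ValueError("drug_mix must sum to 1 within 1e-9")
        for name in (
            "switch_prob",
            "augment_prob",
            "lai_prob",
            "typical_ap_baseline_prob",
            "dual_eligible_prob",
            "enrollment_gap_prob",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.switch_prob + self.augment_prob > 1.0:
            raise ValueError("switch_prob + augment_prob must be <= 1")
        for name in ("hosp_rate", "ed_rate", "outpatient_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hosp_los_mean < 1:
            raise ValueError("hosp_los_mean must be >= 1")
        missing = {"inpatient", "ed", "outpatient", "pharmacy"} - set(self.cost_params)
        if missing:
            raise ValueError(f"cost_params missing settings: {sorted(missing)}")
        return self


def validated_config(**kwargs) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig`, converting pydantic failures into
    :class:`ConfigurationError` messages that name the offending field."""
    try:
        return GeneratorConfig(**kwargs)
    except ValidationError as exc:  # surface the first offending field
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "config"
        raise ConfigurationError(f"{loc}: {first['msg']}") from exc


def load_config(path: str | Path) -> GeneratorConfig:
    """Read a generator configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return validated_config(**data)
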