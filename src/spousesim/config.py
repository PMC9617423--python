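"""Configuration models for simulation, harmonization and analysis.

All tunable parameters live in pydantic models so that a whole run is
reproducible from a single YAML/JSON document plus a seed.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "ConfigurationError",
    "TraitModel",
    "BinaryTraitModel",
    "MedicationModel",
    "TreatmentAdjustmentPolicy",
    "DiseaseCriteria",
    "GeneratorConfig",
    "AnalysisConfig",
    "EDUCATION_CATEGORIES",
]


class ConfigurationError(ValueError):
    """Raised when a configuration value is invalid or inconsistent."""


#: The seven raw education categories collected on the questionnaire.
EDUCATION_CATEGORIES = (
    "elementary or junior high school",
    "high school",
    "vocational school",
    "college or technical college",
    "university",
    "graduate school",
    "other",
)


class TraitModel(BaseModel):
    """Sex-specific linear-in-age model for one continuous trait.

    The marginal value for a person of sex *s* and age *a* is

        mean_s + age_slope_s * (a - age_mean_s) + couple_shared + noise

    with the couple-shared latent factor and the individual noise scaled so
    that the marginal SD equals ``sd_s`` and the within-couple residual
    correlation equals ``couple_corr``.  Traits with ``scale='log10'``
    (triglycerides, MET hours) are modelled on the log10 scale and
    exponentiated on output.
    """

    mean_m: float
    mean_f: float
    sd_m: float = Field(gt=0)
    sd_f: float = Field(gt=0)
    age_slope_m: float = 0.0
    age_slope_f: float = 0.0
    couple_corr: float = Field(0.0, ge=-1.0, le=1.0)
    scale: Literal["linear", "log10"] = "linear"


class BinaryTraitModel(BaseModel):
    """Logistic age model for a binary habit, with a couple effect.

    The female status is drawn from ``logit p = intercept_f + age_slope_f * age``;
    the male status from ``logit p = intercept_m + age_slope_m * age +
    couple_log_or * female_status``, so that ``exp(couple_log_or)`` is exactly
    the age-conditional concordance odds ratio.
    """

    intercept_m: float
    intercept_f: float
    age_slope_m: float = 0.0
    age_slope_f: float = 0.0
    couple_log_or: float = 0.0


class MedicationModel(BaseModel):
    """Thresholded-Bernoulli treatment assignment.

    A person is treated with probability ``prob`` when any trigger trait's
    pre-treatment value meets its threshold, and never otherwise.
    """

    triggers: dict[str, float]
    prob: float = Field(ge=0.0, le=1.0)


class TreatmentAdjustmentPolicy(BaseModel):
    """Constants for reconstructing untreated values in treated individuals.

    Blood pressure under antihypertensive treatment is back-adjusted
    additively; total and LDL cholesterol under lipid-lowering treatment are
    back-adjusted by division.
    """

    sbp_add: float = Field(15.0, ge=0)
    dbp_add: float = Field(10.0, ge=0)
    tc_divisor: float = Field(0.8, gt=0, le=1)
    ldl_divisor: float = Field(0.7, gt=0, le=1)


class DiseaseCriteria(BaseModel):
    """Clinical thresholds for disease flags and analysis filters.

    Metabolic-syndrome components follow the Japanese criteria: the waist
    criterion is mandatory and at least two of the blood-pressure,
    glycaemia and lipid criteria must also be met (medication use counts).
    """

    htn_sbp: float = Field(140.0, gt=0)
    htn_dbp: float = Field(90.0, gt=0)
    dm_hba1c: float = Field(6.5, gt=0)
    mets_waist_m: float = Field(85.0, gt=0)
    mets_waist_f: float = Field(90.0, gt=0)
    mets_sbp: float = Field(130.0, gt=0)
    mets_dbp: float = Field(85.0, gt=0)
    mets_hba1c: float = Field(6.0, gt=0)
    mets_tg: float = Field(150.0, gt=0)
    mets_hdl: float = Field(40.0, gt=0)
    outlier_sd: float = Field(5.0, gt=0)
    activity_percentile: float = Field(80.0, gt=0, lt=100)


class GeneratorConfig(BaseModel):
    """Full parameterization of the synthetic couple-cohort generator."""

    n_pairs: int = Field(ge=0)
    age_mean_m: float
    age_mean_f: float
    age_sd_m: float = Field(gt=0)
    age_sd_f: float = Field(gt=0)
    age_corr: float = Field(ge=-1.0, le=1.0)
    age_min: int = 20
    traits: dict[str, TraitModel] = Field(default_factory=dict)
    binary_traits: dict[str, BinaryTraitModel] = Field(default_factory=dict)
    past_smoker_given_noncurrent_m: float = Field(0.0, ge=0, le=1)
    past_smoker_given_noncurrent_f: float = Field(0.0, ge=0, le=1)
    past_drinker_given_noncurrent_m: float = Field(0.0, ge=0, le=1)
    past_drinker_given_noncurrent_f: float = Field(0.0, ge=0, le=1)
    education_probs_m: dict[str, float] = Field(default_factory=dict)
    education_probs_f: dict[str, float] = Field(default_factory=dict)
    medications: dict[str, MedicationModel] = Field(default_factory=dict)
    treatment: TreatmentAdjustmentPolicy = Field(default_factory=TreatmentAdjustmentPolicy)
    missing_rates: dict[str, float] = Field(default_factory=dict)
    seed: int = 0

    @field_validator("missing_rates")
    @classmethod
    def _rates_in_unit_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for name, rate in v.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing_rates[{name!r}] = {rate} not in [0, 1]")
        return v

    @field_validator("education_probs_m", "education_probs_f")
    @classmethod
    def _education_probs_valid(cls, v: dict[str, float]) -> dict[str, float]:
        if not v:
            return v
        unknown = set(v) - set(EDUCATION_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown education categories: {sorted(unknown)}")
        total = sum(v.values())
        if any(p < 0 for p in v.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError(f"education probabilities must be >= 0 and sum to 1 (got {total})")
        return v

    @model_validator(mode="after")
    def _residual_variance_positive(self) -> "GeneratorConfig":
        # marginal SD must leave room for the age-slope contribution
        for name, t in self.traits.items():
            for s, age_sd in (("m", self.age_sd_m), ("f", self.age_sd_f)):
                sd = getattr(t, f"sd_{s}")
                slope = getattr(t, f"age_slope_{s}")
                if sd**2 <= (slope * age_sd) ** 2:
                    raise ValueError(
                        f"traits[{name!r}]: sd_{s}={sd} too small for age_slope_{s}={slope}"
                    )
        return self

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        try:
            return cls.model_validate(yaml.safe_load(Path(path).read_text()))
        except Exception as exc:  # surface schema violations uniformly
            raise ConfigurationError(str(exc)) from exc


class AnalysisConfig(BaseModel):
    """End-to-end pipeline configuration.

    Either point ``participants_path``/``pairs_path`` at an existing cohort
    or supply a ``generator`` to simulate one.
    """

    participants_path: Optional[str] = None
    pairs_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    seed: int = 0
    level: float = Field(0.95, gt=0, lt=1)
    pairings: Literal["spouse", "randomized", "both"] = "both"
    outdir: str = "output"
    criteria: DiseaseCriteria = Field(default_factory=DiseaseCriteria)
    treatment: TreatmentAdjustmentPolicy = Field(default_factory=TreatmentAdjustmentPolicy)

    @model_validator(mode="after")
    def _has_input(self) -> "AnalysisConfig":
        if self.generator is None and (self.participants_path is None or self.pairs_path is None):
            raise ValueError("either generator or participants_path+pairs_path required")
        return self

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        try:
            return cls.model_validate(yaml.safe_load(Path(path).read_text()))
        except Exception as exc:
            raise ConfigurationError(str(exc)) from exc
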