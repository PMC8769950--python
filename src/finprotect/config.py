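"""Configuration models.

:class:`GeneratorConfig` parameterizes the synthetic household-survey
generator.  Its defaults encode the study conditions the package is designed
around: a two-stage stratified cluster sample of 2304 PSUs x 20 households
drawn from 7 administrative divisions, right-skewed monthly consumption in
Bangladeshi Taka (BDT), a hurdle-type out-of-pocket (OOP) health-payment
process with roughly a quarter of households reporting no health spending,
and covariate effects on the catastrophic-spending odds whose directions and
rough magnitudes mirror published determinants for Bangladesh (chronic
illness, elderly members and private-facility use all strongly raising risk).

Configs are pydantic models: invalid values raise a validation error naming
the offending field, and they serialize to/from YAML or JSON for the CLI.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import ConfigurationError

DIVISIONS = (
    "Barisal",
    "Chittagong",
    "Dhaka",
    "Khulna",
    "Rangpur",
    "Rajshahi",
    "Sylhet",
)

EDUCATION_LEVELS = ("none", "primary", "secondary", "higher_secondary", "university")

QUINTILE_LABELS = ("poorest", "second", "third", "fourth", "richest")

#: Log-odds of facing catastrophic spending at the 10%-of-total threshold,
#: keyed by design-matrix term.  Values are log odds ratios in the range
#: reported for Bangladeshi households (e.g. private facility use exp(2.290)
#: ~ 9.9, chronic-illness care exp(1.546) ~ 4.7).
DEFAULT_LOGIT_BETAS: dict[str, float] = {
    "const": -1.814,
    "head_male": -0.051,
    "edu_primary": 0.028,
    "edu_secondary": 0.011,
    "edu_higher_secondary": -0.017,
    "edu_university": -0.002,
    "has_child": -0.109,
    "has_elderly": 0.275,
    "hhsize_3_4": -0.347,
    "hhsize_5plus": -0.534,
    "chronic_care": 1.546,
    "inpatient_use": 0.076,
    "used_public": 1.415,
    "used_private": 2.290,
    "used_ngo": -2.033,
    "used_other": 0.999,
    "rural": 0.045,
    "div_chittagong": -0.442,
    "div_dhaka": -0.761,
    "div_khulna": -0.832,
    "div_rangpur": -0.766,
    "div_rajshahi": -0.722,
    "div_sylhet": -0.891,
}

#: Multiplicative effects on the magnitude of positive OOP spending.
DEFAULT_OOP_COEFFICIENTS: dict[str, float] = {
    "chronic_care": 2.0,
    "has_elderly": 1.4,
    "inpatient_use": 2.0,
    "used_public": 1.6,
    "used_private": 2.5,
    "used_other": 1.3,
}

#: Marginal prevalence of each binary covariate.
DEFAULT_COVARIATE_PREVALENCES: dict[str, float] = {
    "head_female": 0.128,
    "has_child": 0.720,
    "has_elderly": 0.183,
    "chronic_care": 0.489,
    "inpatient_use": 0.081,
    "used_public": 0.128,
    "used_private": 0.106,
    "used_ngo": 0.031,
    "used_other": 0.388,
}

#: Distribution of household-head education.
DEFAULT_EDUCATION_PROBS: dict[str, float] = {
    "none": 0.421,
    "primary": 0.248,
    "secondary": 0.248,
    "higher_secondary": 0.039,
    "university": 0.044,
}

#: Household-size pmf over 1..9 members (mean ~4.0; 14.3% of households of
#: size 1-2, 52.5% of size 3-4, 33.2% of size 5+).
DEFAULT_HH_SIZE_PMF: dict[int, float] = {
    1: 0.045,
    2: 0.098,
    3: 0.235,
    4: 0.290,
    5: 0.170,
    6: 0.090,
    7: 0.040,
    8: 0.020,
    9: 0.012,
}


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic household-survey generator."""

    model_config = ConfigDict(extra="forbid")

    n_psu: int = Field(default=2304, ge=1)
    households_per_psu: int = Field(default=20, ge=1)
    n_strata: int = Field(default=14, ge=1)
    urban_share: float = Field(default=0.303, ge=0.0, le=1.0)
    divisions: tuple[str, ...] = DIVISIONS
    #: log-scale location of monthly per-capita baseline consumption (BDT).
    consumption_location: float = math.log(3000.0)
    #: log-scale SD of per-capita consumption (total across PSU and
    #: household levels).
    consumption_sigma: float = Field(default=0.50, gt=0.0)
    #: SD of the PSU-level random effect on log consumption (intra-cluster
    #: correlation for the design-based estimators to chew on).
    psu_sigma: float = Field(default=0.15, ge=0.0)
    #: additive log-consumption premium for urban households.
    urban_log_premium: float = 0.25
    #: additive log-consumption premium per education level of the head.
    education_log_premium: float = 0.08
    food_share_mean: float = Field(default=0.50, gt=0.0, lt=1.0)
    #: Engel slope: decline of the food share per unit log consumption.
    engel_slope: float = 0.06
    food_share_concentration: float = Field(default=30.0, gt=2.0)
    #: stratum-level selection probabilities span this range (log-interpolated
    #: across divisions); design weight = 1 / selection probability.
    selection_prob_range: tuple[float, float] = (1.0 / 600.0, 1.0 / 300.0)
    oop_coefficients: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_OOP_COEFFICIENTS)
    )
    logit_true_betas: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_LOGIT_BETAS)
    )
    #: probability of zero OOP among households not flagged catastrophic at
    #: the 10%-of-total threshold; the implied overall any-spending share is
    #: ~75% under the default flag rate.
    zero_oop_prob: float = Field(default=0.33, ge=0.0, le=1.0)
    #: log-mean of the excess ratio above the 10% threshold for flagged
    #: households (before covariate multipliers).
    oop_excess_log_mean: float = math.log(0.4)
    oop_excess_log_sd: float = Field(default=0.7, gt=0.0)
    #: shape of the sub-threshold OOP ratio (larger -> more mass near zero).
    oop_subthreshold_shape: float = Field(default=3.0, gt=0.0)
    #: cap on OOP as a share of total consumption.
    max_oop_share: float = Field(default=0.80, gt=0.1, lt=1.0)
    covariate_prevalences: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    education_probs: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_EDUCATION_PROBS)
    )
    hh_size_pmf: dict[int, float] = Field(
        default_factory=lambda: dict(DEFAULT_HH_SIZE_PMF)
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if len(self.divisions) < 1:
            raise ValueError("divisions: at least one division label required")
        if self.n_psu < 2 * self.n_strata:
            raise ValueError(
                "n_psu: need at least two PSUs per stratum "
                f"(n_psu={self.n_psu}, n_strata={self.n_strata})"
            )
        lo, hi = self.selection_prob_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("selection_prob_range: need 0 < low <= high < 1")
        for name, probs in (
            ("education_probs", self.education_probs),
            ("hh_size_pmf", self.hh_size_pmf),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name}: probabilities must sum to 1, got {total}")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name}: probabilities must be nonnegative")
        for cov, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"covariate_prevalences[{cov}]: fraction in [0,1] required")
        for cov, m in self.oop_coefficients.items():
            if m <= 0:
                raise ValueError(f"oop_coefficients[{cov}]: multiplier must be > 0")
        if set(self.education_probs) != set(EDUCATION_LEVELS):
            raise ValueError("education_probs: keys must be " + ", ".join(EDUCATION_LEVELS))
        if "const" not in self.logit_true_betas:
            raise ValueError("logit_true_betas: must include a 'const' term")
        return self

    @property
    def n_households(self) -> int:
        return self.n_psu * self.households_per_psu

    @classmethod
    def from_yaml(cls, path: str) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        try:
            return cls(**payload)
        except Exception as exc:  # pydantic ValidationError carries field names
            raise ConfigurationError(str(exc)) from exc

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def validated(config: Optional[GeneratorConfig] = None, **overrides) -> GeneratorConfig:
    """Build a config from overrides, translating pydantic validation errors
    into :class:`ConfigurationError` (which names the offending field)."""
    try:
        if config is None:
            return GeneratorConfig(**overrides)
        if not overrides:
            return config
        return GeneratorConfig(**{**config.model_dump(), **overrides})
    except Exception as exc:
        raise ConfigurationError(str(exc)) from exc


RelativeDefinition = Literal["of_gross", "of_net"]
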