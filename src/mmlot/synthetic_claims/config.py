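"""Configuration model for the synthetic claims generator.

All numeric defaults are illustrative: the source data environment publishes
only marginal summaries, so no distributional calibration is attempted.  The
defaults are chosen to exercise every downstream rule (regimen windows,
grace periods, discontinuation gaps, SCT detection, attribution linkage,
follow-up censoring) rather than to look like France.
"""

from __future__ import annotations

import datetime as dt

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class AgeDist(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mean: float
    sd: float = Field(gt=0)


class RegimenOption(BaseModel):
    model_config = ConfigDict(extra="forbid")
    drugs: list[str] = Field(min_length=1)
    prob: float = Field(ge=0.0, le=1.0)


class LotDurationDist(BaseModel):
    """Log-normal LOT duration: ``exp(log(median) + sigma * Z)`` days."""

    model_config = ConfigDict(extra="forbid")
    median_days: float = Field(gt=0)
    sigma: float = Field(ge=0.0)


class CostDist(BaseModel):
    """Log-normal per-event cost: ``exp(log(median) + sigma * Z)`` euros."""

    model_config = ConfigDict(extra="forbid")
    median_eur: float = Field(gt=0)
    sigma: float = Field(ge=0.0)


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_missing_dispensing: float = Field(0.0, ge=0.0, le=1.0)
    p_other_malignancy_history: float = Field(0.0, ge=0.0, le=1.0)
    p_lost_to_followup: float = Field(0.0, ge=0.0, le=1.0)


class ViolationRates(BaseModel):
    """Per-patient probabilities of injected protocol violations."""

    model_config = ConfigDict(extra="forbid")
    untreated: float = Field(0.0, ge=0.0, le=1.0)
    late_start: float = Field(0.0, ge=0.0, le=1.0)
    prior_malignancy: float = Field(0.0, ge=0.0, le=1.0)
    prior_mm: float = Field(0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _total(self):
        total = self.untreated + self.late_start + self.prior_malignancy + self.prior_mm
        if total > 1.0 + 1e-9:
            raise ValueError("violation rates sum above 1")
        return self

    @property
    def items(self) -> list[tuple[str, float]]:
        return [("untreated", self.untreated), ("late_start", self.late_start),
                ("prior_malignancy", self.prior_malignancy), ("prior_mm", self.prior_mm)]


def _default_regimen_menu() -> dict[str, list[RegimenOption]]:
    def opt(drugs, p):
        return RegimenOption(drugs=list(drugs), prob=p)

    return {
        # front line dominated by one proteasome-inhibitor backbone
        "1": [
            opt(("bortezomib", "lenalidomide", "dexamethasone"), 0.40),
            opt(("bortezomib", "thalidomide", "dexamethasone"), 0.25),
            opt(("bortezomib", "melphalan", "prednisone"), 0.20),
            opt(("bortezomib", "cyclophosphamide", "dexamethasone"), 0.10),
            opt(("lenalidomide", "dexamethasone"), 0.05),
        ],
        "2": [
            opt(("lenalidomide", "dexamethasone"), 0.40),
            opt(("bortezomib", "dexamethasone"), 0.20),
            opt(("carfilzomib", "lenalidomide", "dexamethasone"), 0.15),
            opt(("daratumumab", "bortezomib", "dexamethasone"), 0.15),
            opt(("pomalidomide", "dexamethasone"), 0.10),
        ],
        # wider menu for later lines
        "default": [
            opt(("pomalidomide", "dexamethasone"), 0.30),
            opt(("daratumumab",), 0.25),
            opt(("lenalidomide", "dexamethasone"), 0.20),
            opt(("carfilzomib", "dexamethasone"), 0.15),
            opt(("ixazomib", "lenalidomide", "dexamethasone"), 0.10),
        ],
    }


def _default_lot_durations() -> dict[str, LotDurationDist]:
    return {
        "1": LotDurationDist(median_days=240, sigma=0.5),
        "2": LotDurationDist(median_days=180, sigma=0.5),
        "3": LotDurationDist(median_days=130, sigma=0.5),
        "4": LotDurationDist(median_days=90, sigma=0.5),
        "default": LotDurationDist(median_days=65, sigma=0.5),
    }


def _default_cost_distributions() -> dict[str, CostDist]:
    return {
        "dispensing_high_cost": CostDist(median_eur=1500, sigma=0.4),
        "dispensing_temporary_authorised": CostDist(median_eur=3500, sigma=0.4),
        "dispensing_retrocession": CostDist(median_eur=4000, sigma=0.4),
        "dispensing_community": CostDist(median_eur=120, sigma=0.5),
        "stay_mco": CostDist(median_eur=3500, sigma=0.6),
        "stay_chemo": CostDist(median_eur=420, sigma=0.3),
        "stay_home": CostDist(median_eur=1500, sigma=0.4),
        "stay_rehab": CostDist(median_eur=2800, sigma=0.4),
        "stay_emergency": CostDist(median_eur=250, sigma=0.4),
        "stay_sct": CostDist(median_eur=24000, sigma=0.2),
        "physician_visit": CostDist(median_eur=30, sigma=0.3),
        "lab_test": CostDist(median_eur=45, sigma=0.4),
        "medical_procedure": CostDist(median_eur=120, sigma=0.5),
        "other_professional_visit": CostDist(median_eur=35, sigma=0.3),
        "transport": CostDist(median_eur=85, sigma=0.5),
        "medical_device": CostDist(median_eur=160, sigma=0.5),
        "sick_leave_invalidity": CostDist(median_eur=55, sigma=0.3),
    }


class SimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(ge=0)
    seed: int = 0

    history_start: dt.date = dt.date(2008, 1, 1)
    inclusion_start: dt.date = dt.date(2013, 1, 1)
    inclusion_end: dt.date = dt.date(2018, 12, 31)
    study_end: dt.date = dt.date(2018, 12, 31)

    age_distribution: dict[str, AgeDist] = Field(default_factory=lambda: {
        "sct": AgeDist(mean=58, sd=8.0),
        "non_sct": AgeDist(mean=73, sd=9.5),
    })
    sct_probability: float = Field(0.3, ge=0.0, le=1.0)
    #: days from diagnosis to first dispensing, uniform on [0, max]
    treatment_delay_max_days: int = Field(21, ge=0)

    regimen_menu: dict[str, list[RegimenOption]] = Field(
        default_factory=_default_regimen_menu)
    lot_duration: dict[str, LotDurationDist] = Field(
        default_factory=_default_lot_durations)
    n_lot_distribution: dict[str, float] = Field(default_factory=lambda: {
        "0": 0.03, "1": 0.40, "2": 0.27, "3": 0.14, "4": 0.07, "5+": 0.09,
    })
    #: minimum claim-free days inserted after a line's exposure end; must
    #: exceed the discontinuation-gap rule for ground truth to be recoverable
    gap_between_lots_min_days: int = Field(91, gt=0)
    #: mean of the exponential extra gap beyond that minimum
    gap_extra_mean_days: float = Field(45.0, gt=0)
    death_hazard_per_month: dict[str, float] = Field(default_factory=lambda: {
        "sct": 0.005, "non_sct": 0.018,
    })
    cost_distributions: dict[str, CostDist] = Field(
        default_factory=_default_cost_distributions)
    noise: NoiseConfig = NoiseConfig()
    violations: ViolationRates = ViolationRates()

    @field_validator("regimen_menu")
    @classmethod
    def _menus_normalised(cls, v):
        for line, options in v.items():
            total = sum(o.prob for o in options)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"regimen_menu[{line!r}] probabilities sum to {total}, not 1")
        return v

    @field_validator("n_lot_distribution")
    @classmethod
    def _nlot_normalised(cls, v):
        allowed = {"0", "1", "2", "3", "4", "5+"}
        if set(v) - allowed:
            raise ValueError(f"n_lot_distribution keys must be within {sorted(allowed)}")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"n_lot_distribution sums to {total}, not 1")
        if any(p < 0 for p in v.values()):
            raise ValueError("n_lot_distribution has negative mass")
        return v

    @field_validator("death_hazard_per_month")
    @classmethod
    def _hazards(cls, v):
        for k, h in v.items():
            if h < 0:
                raise ValueError(f"death_hazard_per_month[{k!r}] negative")
        return v

    @model_validator(mode="after")
    def _windows(self):
        if not (self.history_start <= self.inclusion_start <= self.inclusion_end
                <= self.study_end):
            raise ValueError("inclusion_window must lie within history_start..study_end")
        if "default" not in self.regimen_menu:
            raise ValueError("regimen_menu requires a 'default' entry")
        if "default" not in self.lot_duration:
            raise ValueError("lot_duration requires a 'default' entry")
        for k in ("sct", "non_sct"):
            if k not in self.age_distribution:
                raise ValueError(f"age_distribution missing stratum {k!r}")
            if k not in self.death_hazard_per_month:
                raise ValueError(f"death_hazard_per_month missing stratum {k!r}")
        return self


def sim_config_json_schema() -> dict:
    """Published JSON schema for the generator config document."""
    return SimConfig.model_json_schema()
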