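"""Pipeline configuration models.

Everything the published text leaves to supplementary material (code lists
for SCT detection, events of interest, malignancy exclusions) is configurable
here, with documented illustrative defaults.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class ConfigError(ValueError):
    pass


def _malignancy_prefixes() -> list[str]:
    # C00–C97 minus myeloma (C90) and non-melanoma skin cancer (C44)
    return [f"C{i:02d}" for i in range(0, 98) if i not in (90, 44)]


class CodeLists(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mm_diagnosis_prefixes: list[str] = ["C90"]
    malignancy_exclusion_prefixes: list[str] = Field(default_factory=_malignancy_prefixes)
    #: stand-in for the unavailable supplementary DRG list; code -> graft type
    sct_drg_codes: dict[str, str] = {"28Z13Z": "autologous", "28Z11Z": "allogeneic"}
    #: stand-in for the unavailable supplementary CCAM list; code -> graft type
    sct_ccam_codes: dict[str, str] = {"FEJF008": "autologous", "FEJF010": "allogeneic"}
    #: primary-diagnosis codes marking a chemotherapy-session stay
    chemo_session_primary_codes: list[str] = ["Z51.1"]
    #: events of interest, matched as ICD-10 prefixes on a stay's primary dx
    aoe_primary_prefixes: list[str] = [
        "D61", "D64", "D69", "D70",        # anaemia / bleeding / cytopenias
        "A41", "B99", "J15", "J18",        # infections incl. pneumonia
        "B02",                             # shingles
        "G62",                             # peripheral neuropathy
        "I26", "I80", "I82",               # VTE / blood clots
        "K52",                             # diarrhoea
        "M80", "M84",                      # skeletal-related events
        "H16", "H25", "H40", "H04",        # ocular events
        "T80",                             # infusion reaction
    ]

    @field_validator("sct_drg_codes", "sct_ccam_codes")
    @classmethod
    def _graft_types(cls, v):
        for code, graft in v.items():
            if graft not in ("autologous", "allogeneic"):
                raise ValueError(f"{code}: graft type must be autologous/allogeneic")
        return v


class EligibilityParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: "older than 18" read literally as >= 19 completed years; switch to
    #: "ge18" to include exact age 18
    age_rule: str = "gt18"
    min_history_days: int = 365
    prior_mm_lookback_days: int = 365
    malignancy_lookback_years: int = 5
    treatment_window_days: int = 30
    followup_gap_days: int = 365

    @field_validator("age_rule")
    @classmethod
    def _age_rule(cls, v):
        if v not in ("gt18", "ge18"):
            raise ValueError("age_rule must be 'gt18' or 'ge18'")
        return v


class LotParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    regimen_window_days: int = Field(28, gt=0)
    gap_days: int = Field(90, gt=0)
    overlap_days: int = Field(40, gt=0)
    #: when True, a drug starting while the current regimen's exposure
    #: demonstrably continues >= overlap_days joins the regimen in place
    #: (combination extension) instead of opening a new line
    combination_extension: bool = True
    include_partially_observable: bool = True
    grace_overrides: dict[str, int] = {}

    @field_validator("grace_overrides")
    @classmethod
    def _positive_grace(cls, v):
        for k, days in v.items():
            if days <= 0:
                raise ValueError(f"grace override for {k} must be positive")
        return v


class CostParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: claim year -> multiplier bringing costs to 2019 prices; None = identity
    price_index: dict[int, float] | None = None
    transport_link_days: int = 1
    sick_leave_link_days: int = 7
    rehab_link_days: int = 1
    #: where ledger items dated between two LOTs attach: "previous" or "drop"
    between_lot_policy: str = "previous"

    @field_validator("between_lot_policy")
    @classmethod
    def _policy(cls, v):
        if v not in ("previous", "drop"):
            raise ValueError("between_lot_policy must be 'previous' or 'drop'")
        return v


class StudyWindow(BaseModel):
    model_config = ConfigDict(extra="forbid")

    history_start: dt.date = dt.date(2008, 1, 1)
    inclusion_start: dt.date = dt.date(2013, 1, 1)
    inclusion_end: dt.date = dt.date(2018, 12, 31)
    study_end: dt.date = dt.date(2018, 12, 31)

    @model_validator(mode="after")
    def _ordered(self):
        if not (self.history_start <= self.inclusion_start <= self.inclusion_end
                <= self.study_end):
            raise ValueError("study window dates out of order")
        return self


class PipelineConfig(BaseModel):
    """Top-level config for the end-to-end pipeline (one section per stage)."""

    model_config = ConfigDict(extra="forbid")

    study_window: StudyWindow = StudyWindow()
    code_lists: CodeLists = CodeLists()
    eligibility: EligibilityParams = EligibilityParams()
    lot: LotParams = LotParams()
    cost: CostParams = CostParams()
    #: backbone precedence used to label regimens, most specific first
    regimen_precedence: list[str] = [
        "daratumumab", "carfilzomib", "ixazomib", "pomalidomide",
        "bortezomib", "lenalidomide", "thalidomide", "bendamustine",
        "melphalan", "cyclophosphamide",
    ]
    simulate: "SimSection | None" = None


class SimSection(BaseModel):
    """Inline synthetic-claims settings inside a pipeline config."""

    model_config = ConfigDict(extra="allow")

    n_patients: int = Field(200, ge=0)
    seed: int = 0


PipelineConfig.model_rebuild()


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON config file into a validated :class:`PipelineConfig`."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    try:
        return PipelineConfig.model_validate(data)
    except ValueError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def config_json_schema() -> dict:
    """Published JSON schema for the pipeline config document."""
    return PipelineConfig.model_json_schema()
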