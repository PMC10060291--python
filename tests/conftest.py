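from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mmlot.catalogue import DrugCatalogue
from mmlot.config import PipelineConfig
from mmlot.schemas import CLAIMS_TABLES

BASE_DATE = pd.Timestamp("2014-01-02")

#: drugs with a 42-day grace period in the default catalogue, used as the
#: generic A/B/C drugs of the segmentation examples
DRUG_A = "lenalidomide"
DRUG_B = "pomalidomide"
DRUG_C = "ixazomib"
EXEMPT = "dexamethasone"

GRACE_42 = {DRUG_A: 42, DRUG_B: 42, DRUG_C: 42}


@pytest.fixture(scope="session")
def catalogue() -> DrugCatalogue:
    return DrugCatalogue.default()


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig()


def day(offset: int) -> pd.Timestamp:
    return BASE_DATE + pd.Timedelta(days=offset)


def dispensings_from_days(events, catalogue=None, patient_id="P1") -> pd.DataFrame:
    """Build a dispensings frame from (drug_name, day_offset) pairs."""
    catalogue = catalogue or DrugCatalogue.default()
    rows = []
    for item in events:
        if len(item) == 3:
            pid, drug, offset = item
        else:
            drug, offset = item
            pid = patient_id
        spec = catalogue.by_name(drug)
        rows.append({"patient_id": pid, "atc_code": spec.atc_code,
                     "drug_label": drug, "dispense_date": day(offset),
                     "setting_class": spec.setting_class, "packs": 1,
                     "cost_eur": 10.0})
    df = pd.DataFrame(rows)
    return CLAIMS_TABLES["dispensings"].validate(df)


def diagnoses_frame(rows) -> pd.DataFrame:
    """rows: (patient_id, icd10_code, date, source)."""
    df = pd.DataFrame(rows, columns=["patient_id", "icd10_code", "date", "source"])
    df["date"] = pd.to_datetime(df["date"])
    return CLAIMS_TABLES["diagnoses"].validate(df)


def patients_frame(rows) -> pd.DataFrame:
    """rows: dicts with patient_id, birth_year, sex, general_scheme, ..."""
    df = pd.DataFrame(rows)
    for col, default in (("sex", "M"), ("general_scheme", True),
                         ("death_date", pd.NaT), ("coverage_end_date", pd.NaT)):
        if col not in df.columns:
            df[col] = default
    return CLAIMS_TABLES["patients"].validate(df)


def stays_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for col, default in (("drg_code", None), ("primary_dx", None),
                         ("related_dx", None), ("associated_dx", None),
                         ("cost_eur", 100.0)):
        if col not in df.columns:
            df[col] = default
    if "discharge_date" not in df.columns:
        df["discharge_date"] = df["admit_date"]
    df["discharge_date"] = df["discharge_date"].fillna(df["admit_date"])
    return CLAIMS_TABLES["stays"].validate(df)


def cost_items_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for col, default in (("days", np.nan), ("code", None)):
        if col not in df.columns:
            df[col] = default
    return CLAIMS_TABLES["cost_items"].validate(df)


def follow_up_frame(rows) -> pd.DataFrame:
    """rows: (patient_id, index_day_offset, end_day_offset, end_reason)."""
    out = []
    for pid, start, end, reason in rows:
        out.append({"patient_id": pid, "index_date": day(start),
                    "end_date": day(end), "end_reason": reason,
                    "months": (end - start) / 30.4375})
    return pd.DataFrame(out)
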