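"""CSV table schemas shared across pipeline stages.

All on-disk tables are plain CSV with fixed headers and ISO-8601 dates.
Each schema knows how to validate and coerce a raw :class:`pandas.DataFrame`
(as read by ``pandas.read_csv``) into the canonical in-memory form: dates as
``datetime64[ns]``, enums checked, costs non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DATE_FORMAT = "%Y-%m-%d"

DIAGNOSIS_SOURCES = (
    "hospital_primary",
    "hospital_related",
    "hospital_associated",
    "long_term_disease",
)

STAY_TYPES = ("mco_complete", "chemo_session", "home", "rehab", "emergency")

DRUG_SETTING_CLASSES = ("high_cost", "temporary_authorised", "retrocession", "community")

COST_ITEM_CATEGORIES = (
    "lab_test",
    "medical_procedure",
    "physician_visit",
    "other_professional_visit",
    "transport",
    "medical_device",
    "sick_leave_invalidity",
)

#: full category enum used by the cost ledger (stays + drugs + outpatient items)
LEDGER_CATEGORIES = (
    "hospitalisation_excl_chemo",
    "chemo_session",
    "home_hospitalisation",
    "rehab",
    "emergency",
    "high_cost_drug",
    "temporary_authorised_drug",
    "retrocession_drug",
    "community_drug",
) + COST_ITEM_CATEGORIES

FOLLOWUP_END_REASONS = ("death", "disenrollment", "lost_to_follow_up", "end_of_observation")

LOT_END_REASONS = ("new_drug", "discontinuation", "censored")


class SchemaError(ValueError):
    """A table failed validation; carries file/row/column context."""

    def __init__(self, message: str, *, file: str | None = None,
                 row: int | None = None, column: str | None = None):
        self.file = file
        self.row = row
        self.column = column
        parts = [message]
        if file is not None:
            parts.append(f"file={file}")
        if row is not None:
            parts.append(f"row={row}")
        if column is not None:
            parts.append(f"column={column}")
        super().__init__(" | ".join(parts))


@dataclass(frozen=True)
class Column:
    name: str
    kind: str  # one of: str, int, float, date, bool, enum
    nullable: bool = False
    choices: tuple[str, ...] = ()
    min_value: float | None = None


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[Column, ...]

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def empty(self) -> pd.DataFrame:
        """An empty frame with the right columns and dtypes (headers-only table)."""
        df = pd.DataFrame({c.name: pd.Series(dtype=_DTYPES[c.kind]) for c in self.columns})
        return df

    def validate(self, df: pd.DataFrame, file: str | None = None) -> pd.DataFrame:
        file = file or self.name
        missing = [c for c in self.column_names if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns {missing}", file=file, column=missing[0])
        out = df.loc[:, self.column_names].copy()
        for col in self.columns:
            out[col.name] = _coerce(out[col.name], col, file)
        return out


_DTYPES = {
    "str": "object",
    "int": "int64",
    "float": "float64",
    "date": "datetime64[ns]",
    "bool": "bool",
    "enum": "object",
}


def _first_bad_row(mask: pd.Series) -> int:
    return int(np.flatnonzero(mask.to_numpy())[0])


def _coerce(s: pd.Series, col: Column, file: str) -> pd.Series:
    if col.kind == "date":
        out = pd.to_datetime(s, format="mixed", errors="coerce")
        bad = out.isna() & s.notna() & (s.astype(str).str.strip() != "")
        if bad.any():
            raise SchemaError("unparseable date", file=file,
                              row=_first_bad_row(bad), column=col.name)
        if not col.nullable and out.isna().any():
            raise SchemaError("missing date", file=file,
                              row=_first_bad_row(out.isna()), column=col.name)
        return out
    if col.kind in ("int", "float"):
        out = pd.to_numeric(s, errors="coerce")
        bad = out.isna() & s.notna()
        if bad.any():
            raise SchemaError("non-numeric value", file=file,
                              row=_first_bad_row(bad), column=col.name)
        if not col.nullable and out.isna().any():
            raise SchemaError("missing value", file=file,
                              row=_first_bad_row(out.isna()), column=col.name)
        if col.min_value is not None:
            bad = out.notna() & (out < col.min_value)
            if bad.any():
                raise SchemaError(f"value below minimum {col.min_value}", file=file,
                                  row=_first_bad_row(bad), column=col.name)
        if col.kind == "int" and not out.isna().any():
            out = out.astype("int64")
        return out
    if col.kind == "bool":
        mapping = {"true": True, "false": False, "1": True, "0": False,
                   True: True, False: False, 1: True, 0: False, 1.0: True, 0.0: False}
        lowered = s.map(lambda v: mapping.get(v.strip().lower() if isinstance(v, str) else v))
        if lowered.isna().any():
            raise SchemaError("not a boolean", file=file,
                              row=_first_bad_row(lowered.isna()), column=col.name)
        return lowered.astype(bool)
    if col.kind == "enum":
        vals = s.astype(str)
        if col.nullable:
            blank = s.isna() | (vals.str.strip() == "")
        else:
            blank = pd.Series(False, index=s.index)
        bad = ~vals.isin(col.choices) & ~blank
        if bad.any():
            raise SchemaError(f"value not in {col.choices}", file=file,
                              row=_first_bad_row(bad), column=col.name)
        out = vals.where(~blank, other=None)
        return out
    # str
    out = s.astype(str).where(s.notna(), other=None)
    if not col.nullable:
        blank = s.isna() | (out.fillna("").str.strip() == "")
        if blank.any():
            raise SchemaError("missing value", file=file,
                              row=_first_bad_row(blank), column=col.name)
    return out


PATIENTS = TableSchema("patients.csv", (
    Column("patient_id", "str"),
    Column("birth_year", "int", min_value=1900),
    Column("sex", "enum", choices=("M", "F")),
    Column("general_scheme", "bool"),
    Column("death_date", "date", nullable=True),
    Column("coverage_end_date", "date", nullable=True),
))

DIAGNOSES = TableSchema("diagnoses.csv", (
    Column("patient_id", "str"),
    Column("icd10_code", "str"),
    Column("date", "date"),
    Column("source", "enum", choices=DIAGNOSIS_SOURCES),
))

DISPENSINGS = TableSchema("dispensings.csv", (
    Column("patient_id", "str"),
    Column("atc_code", "str"),
    Column("drug_label", "str"),
    Column("dispense_date", "date"),
    Column("setting_class", "enum", choices=DRUG_SETTING_CLASSES),
    Column("packs", "int", min_value=0),
    Column("cost_eur", "float", min_value=0.0),
))

STAYS = TableSchema("stays.csv", (
    Column("patient_id", "str"),
    Column("admit_date", "date"),
    Column("discharge_date", "date"),
    Column("stay_type", "enum", choices=STAY_TYPES),
    Column("drg_code", "str", nullable=True),
    Column("primary_dx", "str", nullable=True),
    Column("related_dx", "str", nullable=True),
    Column("associated_dx", "str", nullable=True),
    Column("cost_eur", "float", min_value=0.0),
))

COST_ITEMS = TableSchema("cost_items.csv", (
    Column("patient_id", "str"),
    Column("date", "date"),
    Column("category", "enum", choices=COST_ITEM_CATEGORIES),
    Column("cost_eur", "float", min_value=0.0),
    Column("days", "float", nullable=True, min_value=0.0),
    Column("code", "str", nullable=True),
))

GROUND_TRUTH = TableSchema("ground_truth.csv", (
    Column("patient_id", "str"),
    Column("true_index_date", "date"),
    Column("true_eligible", "bool"),
    Column("true_fail_reason", "str", nullable=True),
    Column("true_n_lots", "int", min_value=0),
    Column("true_lot_json", "str", nullable=True),
    Column("true_sct", "bool"),
    Column("true_sct_date", "date", nullable=True),
    Column("true_death_date", "date", nullable=True),
    Column("true_followup_end", "date", nullable=True),
    Column("true_end_reason", "enum", nullable=True, choices=FOLLOWUP_END_REASONS),
))

COHORT = TableSchema("cohort.csv", (
    Column("patient_id", "str"),
    Column("index_date", "date"),
    Column("birth_year", "int"),
    Column("sex", "enum", choices=("M", "F")),
    Column("age_at_index", "int"),
))

FOLLOWUP = TableSchema("followup.csv", (
    Column("patient_id", "str"),
    Column("index_date", "date"),
    Column("end_date", "date"),
    Column("end_reason", "enum", choices=FOLLOWUP_END_REASONS),
    Column("months", "float", min_value=0.0),
))

EXCLUSION_LOG = TableSchema("exclusion_log.csv", (
    Column("patient_id", "str"),
    Column("rule", "str"),
    Column("evidence", "str", nullable=True),
))

LOTS = TableSchema("lots.csv", (
    Column("patient_id", "str"),
    Column("lot_number", "int", min_value=1),
    Column("regimen", "str"),
    Column("regimen_label", "str", nullable=True),
    Column("start", "date"),
    Column("end", "date"),
    Column("end_reason", "enum", choices=LOT_END_REASONS),
    Column("duration_days", "int", min_value=0),
))

CLAIMS_TABLES = {
    "patients": PATIENTS,
    "diagnoses": DIAGNOSES,
    "dispensings": DISPENSINGS,
    "stays": STAYS,
    "cost_items": COST_ITEMS,
}


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.mask(df == "")
    return schema.validate(df, file=str(path))


def write_table(df: pd.DataFrame, path, schema: TableSchema | None = None) -> None:
    """Write a table as CSV with ISO dates; byte-stable for identical frames."""
    out = df.copy()
    if schema is not None:
        order = [c for c in schema.column_names if c in out.columns]
        out = out.loc[:, order]
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime(DATE_FORMAT)
    out.to_csv(path, index=False, lineterminator="\n")
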