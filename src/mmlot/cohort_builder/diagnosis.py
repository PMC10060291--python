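"""Diagnosis confirmation and index-date assignment."""

from __future__ import annotations

import datetime as dt

import pandas as pd

_HOSPITAL_SOURCES = ("hospital_primary", "hospital_related", "hospital_associated")


def _matches_any_prefix(codes: pd.Series, prefixes) -> pd.Series:
    out = pd.Series(False, index=codes.index)
    for p in prefixes:
        out |= codes.str.startswith(p)
    return out


def confirm_mm_diagnosis(diagnoses: pd.DataFrame,
                         inclusion_start, inclusion_end,
                         mm_prefixes=("C90",),
                         distinct_dates: bool = True) -> pd.DataFrame:
    """Per-patient diagnosis confirmation flag and candidate index date.

    A patient is confirmed when they have at least two hospital-stay records
    of the diagnosis (on distinct dates when ``distinct_dates``, the default,
    as a proxy for distinct stays), or at least one hospital-stay record plus
    a long-term-disease registration.  The candidate index date is the
    earliest matching diagnosis of any source inside the inclusion window;
    ``NaT`` when no record falls inside it.

    Returns a frame with columns ``patient_id``, ``confirmed``,
    ``candidate_index_date``.
    """
    inclusion_start = pd.Timestamp(inclusion_start)
    inclusion_end = pd.Timestamp(inclusion_end)
    mm = diagnoses.loc[_matches_any_prefix(diagnoses["icd10_code"], mm_prefixes)]

    all_ids = diagnoses["patient_id"].unique()
    if mm.empty:
        return pd.DataFrame({"patient_id": sorted(all_ids),
                             "confirmed": False,
                             "candidate_index_date": pd.NaT})

    hosp = mm.loc[mm["source"].isin(_HOSPITAL_SOURCES)]
    if distinct_dates:
        n_hosp = hosp.groupby("patient_id")["date"].nunique()
    else:
        n_hosp = hosp.groupby("patient_id").size()
    has_ltd = mm.loc[mm["source"] == "long_term_disease"].groupby("patient_id").size() > 0

    in_window = mm.loc[(mm["date"] >= inclusion_start) & (mm["date"] <= inclusion_end)]
    earliest = in_window.groupby("patient_id")["date"].min()

    out = pd.DataFrame({"patient_id": sorted(all_ids)})
    out["n_hospital_records"] = out["patient_id"].map(n_hosp).fillna(0).astype(int)
    out["has_ltd"] = out["patient_id"].map(has_ltd).astype("boolean").fillna(False).astype(bool)
    out["confirmed"] = (out["n_hospital_records"] >= 2) | (
        (out["n_hospital_records"] >= 1) & out["has_ltd"])
    out["candidate_index_date"] = out["patient_id"].map(earliest)
    return out[["patient_id", "confirmed", "candidate_index_date"]]


def set_index_date(confirmation: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split confirmed patients into (indexed, dropped-with-reason).

    ``indexed`` has columns ``patient_id``, ``index_date``; ``dropped``
    has ``patient_id``, ``rule`` explaining why no index could be set.
    """
    confirmed = confirmation.loc[confirmation["confirmed"]]
    has_index = confirmed["candidate_index_date"].notna()
    indexed = confirmed.loc[has_index, ["patient_id", "candidate_index_date"]].rename(
        columns={"candidate_index_date": "index_date"}).reset_index(drop=True)
    dropped_rows = []
    for pid in confirmation.loc[~confirmation["confirmed"], "patient_id"]:
        dropped_rows.append({"patient_id": pid, "rule": "diagnosis_not_confirmed"})
    for pid in confirmed.loc[~has_index, "patient_id"]:
        dropped_rows.append({"patient_id": pid, "rule": "no_diagnosis_in_window"})
    dropped = pd.DataFrame(dropped_rows, columns=["patient_id", "rule"])
    return indexed, dropped
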