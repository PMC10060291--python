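"""Eligibility rules, applied in a fixed order with first-failure reporting.

Rule order (identifiers double as exclusion-log labels):

1. ``missing_data``       — demographics absent
2. ``age_over_18``        — "older than 18" at index (>= 19 completed years
   by default; configurable to >= 18)
3. ``general_scheme``     — affiliation flag on the patient record
4. ``insufficient_history`` — < 365 observable days before index
5. ``prior_mm``           — an MM diagnosis record strictly inside
   (index - 365 d, index)
6. ``other_malignancy``   — any other-malignancy record (C00–C97 excluding
   C90 and C44) in [index - 5 y, index)
7. ``no_mm_treatment`` / ``treatment_after_30d`` — no MM-indicated
   dispensing in [index, index + 30 d]; split by whether the patient was
   ever treated, so attrition strata can be reported separately
"""

from __future__ import annotations

import pandas as pd

from mmlot.catalogue import DrugCatalogue
from mmlot.cohort_builder.diagnosis import _matches_any_prefix
from mmlot.config import CodeLists, EligibilityParams

RULE_ORDER = (
    "missing_data",
    "age_over_18",
    "general_scheme",
    "insufficient_history",
    "prior_mm",
    "other_malignancy",
    "no_mm_treatment",
    "treatment_after_30d",
)


def apply_eligibility(patients: pd.DataFrame,
                      diagnoses: pd.DataFrame,
                      dispensings: pd.DataFrame,
                      index_dates: pd.DataFrame,
                      catalogue: DrugCatalogue | None = None,
                      params: EligibilityParams | None = None,
                      code_lists: CodeLists | None = None,
                      history_start=None) -> pd.DataFrame:
    """Evaluate all rules per indexed patient; return one verdict per patient.

    Output columns: ``patient_id``, ``index_date``, ``eligible``,
    ``first_failed_rule`` (None when eligible), ``evidence``.
    """
    catalogue = catalogue or DrugCatalogue.default()
    params = params or EligibilityParams()
    code_lists = code_lists or CodeLists()
    history_start = pd.Timestamp(history_start) if history_start is not None else None

    pat = patients.set_index("patient_id")
    mm_mask = _matches_any_prefix(diagnoses["icd10_code"], code_lists.mm_diagnosis_prefixes)
    mm_diag = diagnoses.loc[mm_mask]
    malig_mask = _matches_any_prefix(
        diagnoses["icd10_code"], code_lists.malignancy_exclusion_prefixes)
    # defensive: the default prefix list already omits C90/C44 but a custom
    # list must never re-include the disease itself
    malig_mask &= ~mm_mask
    malig_diag = diagnoses.loc[malig_mask]

    mm_codes = {c.atc_code for c in catalogue if c.mm_indicated}
    mm_disp = dispensings.loc[dispensings["atc_code"].isin(mm_codes)]

    mm_diag_by_pid = dict(tuple(mm_diag.groupby("patient_id")["date"]))
    malig_by_pid = dict(tuple(malig_diag.groupby("patient_id")))
    disp_by_pid = dict(tuple(mm_disp.groupby("patient_id")["dispense_date"]))

    rows = []
    for rec in index_dates.sort_values("patient_id").itertuples(index=False):
        pid, index = rec.patient_id, pd.Timestamp(rec.index_date)
        rule, evidence = _first_failure(
            pid, index, pat, mm_diag_by_pid, malig_by_pid, disp_by_pid,
            params, history_start)
        rows.append({"patient_id": pid, "index_date": index,
                     "eligible": rule is None, "first_failed_rule": rule,
                     "evidence": evidence})
    return pd.DataFrame(rows, columns=["patient_id", "index_date", "eligible",
                                       "first_failed_rule", "evidence"])


def _first_failure(pid, index, pat, mm_diag_by_pid, malig_by_pid, disp_by_pid,
                   params: EligibilityParams, history_start):
    if pid not in pat.index:
        return "missing_data", "no demographics record"
    demo = pat.loc[pid]
    if pd.isna(demo["birth_year"]):
        return "missing_data", "birth_year missing"

    age = index.year - int(demo["birth_year"])
    min_age = 19 if params.age_rule == "gt18" else 18
    if age < min_age:
        return "age_over_18", f"age {age} at index"

    if not bool(demo["general_scheme"]):
        return "general_scheme", "not affiliated with general scheme"

    if history_start is not None:
        history_days = (index - history_start).days
        if history_days < params.min_history_days:
            return "insufficient_history", f"{history_days} days of history"

    dates = mm_diag_by_pid.get(pid)
    if dates is not None:
        lo = index - pd.Timedelta(days=params.prior_mm_lookback_days)
        prior = dates[(dates > lo) & (dates < index)]
        if len(prior):
            return "prior_mm", f"MM record on {prior.min().date()}"

    malig = malig_by_pid.get(pid)
    if malig is not None:
        lo = index - pd.DateOffset(years=params.malignancy_lookback_years)
        hit = malig[(malig["date"] >= lo) & (malig["date"] < index)]
        if len(hit):
            first = hit.sort_values("date").iloc[0]
            return "other_malignancy", (f"{first['icd10_code']} on "
                                        f"{first['date'].date()}")

    disp = disp_by_pid.get(pid)
    if disp is None or not len(disp):
        return "no_mm_treatment", "no MM-indicated dispensing"
    window_end = index + pd.Timedelta(days=params.treatment_window_days)
    in_window = disp[(disp >= index) & (disp <= window_end)]
    if not len(in_window):
        return "treatment_after_30d", f"first dispensing {disp.min().date()}"
    return None, f"first dispensing {in_window.min().date()}"
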