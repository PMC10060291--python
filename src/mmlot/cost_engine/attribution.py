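"""Cost attribution flags.

``mm_treatment_admin`` marks costs of administering disease-directed drug
treatment: MM-indicated drug dispensings in any setting, chemotherapy-session
stays carrying the disease as related diagnosis (whole stay cost), transport
on the day of or the day after such a treatment event, and sick leave
starting within seven days of one.  ``mm_related`` is a superset adding
stays with a primary or associated disease diagnosis, home hospitalisation
with a disease diagnosis, and rehabilitation stays directly following a
flagged stay; outpatient tests, procedures, physician visits, and devices
are never flagged.  Flags are monotone: admin implies related.
"""

from __future__ import annotations

import pandas as pd

from mmlot.catalogue import DrugCatalogue
from mmlot.config import CodeLists, CostParams
from mmlot.cost_engine.ledger import DRUG_CATEGORIES

#: outpatient categories excluded from the disease-related analysis
MM_RELATED_EXCLUDED = ("lab_test", "medical_procedure", "physician_visit",
                       "medical_device")


def _startswith_any(series: pd.Series, prefixes) -> pd.Series:
    s = series.fillna("").astype(str)
    out = pd.Series(False, index=series.index)
    for p in prefixes:
        out |= s.str.startswith(p)
    return out


def tag_mm_treatment_admin(ledger: pd.DataFrame,
                           catalogue: DrugCatalogue | None = None,
                           code_lists: CodeLists | None = None,
                           cost_params: CostParams | None = None) -> pd.DataFrame:
    """Return the ledger with a boolean ``mm_treatment_admin`` column."""
    catalogue = catalogue or DrugCatalogue.default()
    code_lists = code_lists or CodeLists()
    cost_params = cost_params or CostParams()

    flag = pd.Series(False, index=ledger.index)

    mm_atc = {s.atc_code for s in catalogue if s.mm_indicated}
    drug_rows = ledger["category"].isin(DRUG_CATEGORIES)
    flag |= drug_rows & ledger["atc_code"].isin(mm_atc)

    chemo_primary = ledger["primary_dx"].isin(code_lists.chemo_session_primary_codes)
    mm_related_dx = _startswith_any(ledger["related_dx"],
                                    code_lists.mm_diagnosis_prefixes)
    stay_rows = ledger["source_table"] == "stays"
    flag |= stay_rows & chemo_primary & mm_related_dx

    # linkage: transport on/next day, sick leave starting within 7 days of a
    # flagged treatment event (dispensing date or flagged-stay discharge)
    events = pd.concat([
        ledger.loc[flag & drug_rows, ["patient_id", "date"]]
        .rename(columns={"date": "event"}),
        ledger.loc[flag & stay_rows, ["patient_id", "discharge_date"]]
        .rename(columns={"discharge_date": "event"}),
    ], ignore_index=True).dropna()
    events_by_pid = {pid: sorted(g["event"]) for pid, g in events.groupby("patient_id")}

    for category, link_days in (("transport", cost_params.transport_link_days),
                                ("sick_leave_invalidity",
                                 cost_params.sick_leave_link_days)):
        rows = ledger.index[ledger["category"] == category]
        link = pd.Timedelta(days=link_days)
        for i in rows:
            pid, d = ledger.at[i, "patient_id"], ledger.at[i, "date"]
            for e in events_by_pid.get(pid, ()):
                if e > d:
                    break
                if d - e <= link:
                    flag.at[i] = True
                    break

    out = ledger.copy()
    out["mm_treatment_admin"] = flag
    return out


def tag_mm_related(ledger: pd.DataFrame,
                   code_lists: CodeLists | None = None,
                   cost_params: CostParams | None = None) -> pd.DataFrame:
    """Return the ledger with ``mm_related`` added (requires admin flags)."""
    if "mm_treatment_admin" not in ledger.columns:
        raise ValueError("run tag_mm_treatment_admin first")
    code_lists = code_lists or CodeLists()
    cost_params = cost_params or CostParams()

    flag = ledger["mm_treatment_admin"].copy()
    stay_rows = ledger["source_table"] == "stays"
    mm_primary = _startswith_any(ledger["primary_dx"], code_lists.mm_diagnosis_prefixes)
    mm_related_dx = _startswith_any(ledger["related_dx"], code_lists.mm_diagnosis_prefixes)
    mm_assoc = _startswith_any(ledger["associated_dx"], code_lists.mm_diagnosis_prefixes)

    flag |= stay_rows & (mm_primary | mm_assoc)
    flag |= stay_rows & (ledger["stay_type"] == "home") & (
        mm_primary | mm_related_dx | mm_assoc)

    # rehab stays directly following a flagged stay (fixpoint over chains)
    link = pd.Timedelta(days=cost_params.rehab_link_days)
    rehab_idx = ledger.index[stay_rows & (ledger["stay_type"] == "rehab")]
    changed = True
    while changed:
        changed = False
        discharges = {
            pid: sorted(g["discharge_date"].dropna())
            for pid, g in ledger.loc[flag & stay_rows].groupby("patient_id")}
        for i in rehab_idx:
            if flag.at[i]:
                continue
            pid, admit = ledger.at[i, "patient_id"], ledger.at[i, "date"]
            for e in discharges.get(pid, ()):
                if e > admit:
                    break
                if admit - e <= link:
                    flag.at[i] = True
                    changed = True
                    break

    flag &= ~ledger["category"].isin(MM_RELATED_EXCLUDED)
    flag |= ledger["mm_treatment_admin"]  # keep monotone even with odd configs

    out = ledger.copy()
    out["mm_related"] = flag
    return out
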