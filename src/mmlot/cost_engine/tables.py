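"""Report-shaped cost aggregation.

Three shapes are produced, all at full precision (rendering to the printed
K€/M€ precision happens in :mod:`mmlot.reporting`):

* an all-cause cost table (category rows, subtotal and total rows, overall
  and first-year columns);
* a per-category HCRU rate report (users, events PPPY, costs);
* a disease-treatment-administration cost table stratified by line of
  therapy and transplant status.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mmlot.config import CostParams
from mmlot.cost_engine.ledger import DRUG_CATEGORIES, HOSPITAL_CATEGORIES
from mmlot.cost_engine.rates import (
    clip_first_year,
    first_year_person_months,
    person_months,
    person_years,
    pppm,
    pppy,
)

OTHER_CATEGORIES = ("lab_test", "medical_procedure", "physician_visit",
                    "other_professional_visit", "transport", "medical_device",
                    "sick_leave_invalidity")

ALLCAUSE_ROW_ORDER = (
    list(HOSPITAL_CATEGORIES) + ["all_hospitalisation"]
    + list(DRUG_CATEGORIES) + ["all_treatment"]
    + list(OTHER_CATEGORIES) + ["all_other", "total"]
)

_SUBTOTALS = {
    "all_hospitalisation": HOSPITAL_CATEGORIES,
    "all_treatment": DRUG_CATEGORIES,
    "all_other": OTHER_CATEGORIES,
    "total": HOSPITAL_CATEGORIES + DRUG_CATEGORIES + OTHER_CATEGORIES,
}


def assign_lot_numbers(ledger: pd.DataFrame, lots: pd.DataFrame,
                       between_lot_policy: str = "previous",
                       date_col: str = "date") -> pd.Series:
    """Line number each ledger row falls into; <NA> when unattributable.

    A row belongs to the line whose start is the latest one on or before the
    row's date.  Rows dated after a line's end but before the next line start
    either stay with the previous line (default) or are dropped (``"drop"``).
    Rows before the first line start are never attributed.
    """
    out = pd.Series(pd.NA, index=ledger.index, dtype="Int64")
    if not len(lots):
        return out
    by_pid = {pid: g.sort_values("start") for pid, g in lots.groupby("patient_id")}
    for pid, grp in ledger.groupby("patient_id"):
        mine = by_pid.get(pid)
        if mine is None:
            continue
        starts = mine["start"].to_numpy()
        ends = mine["end"].to_numpy()
        numbers = mine["lot_number"].to_numpy()
        pos = np.searchsorted(starts, grp[date_col].to_numpy(), side="right") - 1
        values = np.where(pos >= 0, numbers[np.clip(pos, 0, None)], -1)
        if between_lot_policy == "drop":
            inside = (pos >= 0) & (grp[date_col].to_numpy()
                                   <= ends[np.clip(pos, 0, None)])
            values = np.where(inside, values, -1)
        series = pd.Series(values, index=grp.index).astype("Int64")
        out.loc[grp.index] = series.where(series >= 0, pd.NA)
    return out


def _sums_by_category(ledger: pd.DataFrame) -> pd.Series:
    return ledger.groupby("category")["cost_eur_2019"].sum()


def build_allcause_table(ledger: pd.DataFrame, follow_ups: pd.DataFrame) -> pd.DataFrame:
    """All-cause cost table (full precision euros) for one stratum.

    Columns: ``sum_eur``, ``mean_pp_eur``, ``share_pct``, ``pppy_eur``,
    ``fy_sum_eur``, ``fy_mean_pp_eur``, ``fy_share_pct``, ``fy_pppm_eur``.
    Subtotal rows are exact sums of their member categories.
    """
    n = len(follow_ups)
    years = person_years(follow_ups)
    fy_months = first_year_person_months(follow_ups)
    sums = _sums_by_category(ledger)
    fy_sums = _sums_by_category(clip_first_year(ledger, follow_ups))

    def row_sum(key, table):
        if key in _SUBTOTALS:
            return float(sum(table.get(c, 0.0) for c in _SUBTOTALS[key]))
        return float(table.get(key, 0.0))

    total = row_sum("total", sums)
    fy_total = row_sum("total", fy_sums)
    rows = []
    for key in ALLCAUSE_ROW_ORDER:
        s, fs = row_sum(key, sums), row_sum(key, fy_sums)
        rows.append({
            "row": key,
            "sum_eur": s,
            "mean_pp_eur": s / n if n else np.nan,
            "share_pct": 100.0 * s / total if total else np.nan,
            "pppy_eur": pppy(s, years),
            "fy_sum_eur": fs,
            "fy_mean_pp_eur": fs / n if n else np.nan,
            "fy_share_pct": 100.0 * fs / fy_total if fy_total else np.nan,
            "fy_pppm_eur": pppm(fs, fy_months),
        })
    return pd.DataFrame(rows).set_index("row")


def rate_report(ledger: pd.DataFrame, follow_ups: pd.DataFrame) -> pd.DataFrame:
    """Per-category users, event rates and cost rates for one stratum.

    Events are ledger rows except for day-denominated categories (sick
    leave), which count their ``days`` field.
    """
    n = len(follow_ups)
    years = person_years(follow_ups)
    fy_months = first_year_person_months(follow_ups)
    fy_ledger = clip_first_year(ledger, follow_ups)
    total = float(ledger["cost_eur_2019"].sum())
    rows = []
    for category in HOSPITAL_CATEGORIES + DRUG_CATEGORIES + OTHER_CATEGORIES:
        sub = ledger.loc[ledger["category"] == category]
        fy_sub = fy_ledger.loc[fy_ledger["category"] == category]
        users = sub["patient_id"].nunique()
        if category == "sick_leave_invalidity":
            events = float(sub["days"].fillna(1).sum())
        else:
            events = float(len(sub))
        cost = float(sub["cost_eur_2019"].sum())
        rows.append({
            "category": category,
            "n_users": int(users),
            "pct_users": 100.0 * users / n if n else np.nan,
            "rate_pppy": pppy(events, years),
            "cost_sum": cost,
            "cost_mean_pp": cost / n if n else np.nan,
            "cost_pppy": pppy(cost, years),
            "cost_pppm_first_year": pppm(float(fy_sub["cost_eur_2019"].sum()),
                                         fy_months),
            "share_pct": 100.0 * cost / total if total else np.nan,
        })
    return pd.DataFrame(rows).set_index("category")


# ---------------------------------------------------------------------------
# disease-treatment-administration costs by line of therapy

ADMIN_ROW_ORDER = (
    "chemo_session", "high_cost_drug", "temporary_authorised_drug",
    "retrocession_drug", "community_drug", "mm_treatment", "transport",
    "sick_leave_invalidity", "total",
)

_ADMIN_SUBTOTALS = {
    "mm_treatment": DRUG_CATEGORIES,
    "total": ("chemo_session",) + DRUG_CATEGORIES + (
        "transport", "sick_leave_invalidity"),
}


def _line_intervals(lots: pd.DataFrame, follow_ups: pd.DataFrame) -> pd.DataFrame:
    """Per (patient, line): attribution interval [start, stop] inclusive."""
    fu = follow_ups.set_index("patient_id")
    rows = []
    for pid, grp in lots.groupby("patient_id"):
        grp = grp.sort_values("lot_number")
        starts = list(grp["start"])
        fu_end = fu.loc[pid, "end_date"] if pid in fu.index else grp["end"].max()
        for i, rec in enumerate(grp.itertuples(index=False)):
            stop = (starts[i + 1] - pd.Timedelta(days=1)
                    if i + 1 < len(starts) else fu_end)
            rows.append({"patient_id": pid, "lot_number": rec.lot_number,
                         "start": rec.start, "stop": max(stop, rec.start),
                         "index_date": fu.loc[pid, "index_date"]
                         if pid in fu.index else rec.start})
    return pd.DataFrame(rows, columns=["patient_id", "lot_number", "start",
                                       "stop", "index_date"])


def build_mm_admin_by_lot(ledger: pd.DataFrame, follow_ups: pd.DataFrame,
                          sct: pd.DataFrame, lots: pd.DataFrame,
                          cost_params: CostParams | None = None,
                          max_line: int = 5) -> pd.DataFrame:
    """Treatment-administration cost table by line / transplant strata.

    Requires ``mm_treatment_admin`` flags on the ledger.  Returns a tidy
    frame with columns ``block`` (``mean_pp_eur`` / ``sum_eur`` /
    ``fy_pppm_eur``), ``row``, ``stratum`` and ``value`` (euros), plus an
    ``n`` column giving each stratum's patient count.  The share row uses
    the stratum's total all-cause cost as denominator.
    """
    cost_params = cost_params or CostParams()
    admin = ledger.loc[ledger["mm_treatment_admin"]].copy()
    lot_of_row = assign_lot_numbers(admin, lots, cost_params.between_lot_policy)
    admin["line"] = lot_of_row
    all_lot_of_row = assign_lot_numbers(ledger, lots, cost_params.between_lot_policy)

    intervals = _line_intervals(lots, follow_ups)
    sct_ids = set(sct.loc[sct["sct"], "patient_id"]) if len(sct) else set()
    max_lots = lots.groupby("patient_id")["lot_number"].max() if len(lots) else pd.Series(dtype=int)

    strata: list[tuple[str, pd.Series, set | None]] = []
    for line in range(1, max_line + 1):
        last = line == max_line
        name = f"lot{line}+" if last else f"lot{line}"
        line_mask = (admin["line"] >= line) if last else (admin["line"] == line)
        patients = set(max_lots.index[max_lots >= line])
        strata.append((name, line_mask, patients))
    strata.append(("sct", admin["patient_id"].isin(sct_ids), sct_ids))
    strata.append(("total", pd.Series(True, index=admin.index),
                   set(follow_ups["patient_id"])))

    fy_cut = follow_ups.set_index("patient_id")["index_date"] + pd.Timedelta(days=365)
    admin_fy = admin.loc[admin["date"] <= admin["patient_id"].map(fy_cut)]

    rows = []
    for name, mask, patients in strata:
        n = len(patients)
        sub = admin.loc[mask]
        sub_fy = admin_fy.loc[mask.reindex(admin_fy.index, fill_value=False)]
        if name.startswith("lot"):
            line = int(name.rstrip("+").replace("lot", ""))
            plus = name.endswith("+")
            fy_m = _line_first_year_months(intervals, line, plus)
            stratum_total = float(
                ledger.loc[(all_lot_of_row >= line) if plus
                           else (all_lot_of_row == line), "cost_eur_2019"].sum())
        else:
            ids = patients
            fu_sub = follow_ups.loc[follow_ups["patient_id"].isin(ids)]
            fy_m = first_year_person_months(fu_sub)
            stratum_total = float(
                ledger.loc[ledger["patient_id"].isin(ids), "cost_eur_2019"].sum())

        sums = _sums_by_category(sub)
        fy_sums = _sums_by_category(sub_fy)

        def value(key, table):
            if key in _ADMIN_SUBTOTALS:
                return float(sum(table.get(c, 0.0) for c in _ADMIN_SUBTOTALS[key]))
            return float(table.get(key, 0.0))

        for key in ADMIN_ROW_ORDER:
            s, fs = value(key, sums), value(key, fy_sums)
            rows.append({"block": "sum_eur", "row": key, "stratum": name,
                         "value": s, "n": n})
            rows.append({"block": "mean_pp_eur", "row": key, "stratum": name,
                         "value": s / n if n else np.nan, "n": n})
            rows.append({"block": "fy_pppm_eur", "row": key, "stratum": name,
                         "value": pppm(fs, fy_m), "n": n})
        total_admin = value("total", sums)
        rows.append({"block": "share_of_stratum_total_pct", "row": "total",
                     "stratum": name,
                     "value": 100.0 * total_admin / stratum_total
                     if stratum_total else np.nan, "n": n})
    return pd.DataFrame(rows, columns=["block", "row", "stratum", "value", "n"])


def _line_first_year_months(intervals: pd.DataFrame, line: int, plus: bool) -> float:
    if not len(intervals):
        return 0.0
    sel = intervals.loc[intervals["lot_number"] >= line] if plus else \
        intervals.loc[intervals["lot_number"] == line]
    days = 0
    for rec in sel.itertuples(index=False):
        fy_end = rec.index_date + pd.Timedelta(days=365)
        lo, hi = max(rec.start, rec.index_date), min(rec.stop, fy_end)
        if hi >= lo:
            days += (hi - lo).days + 1
    return days / 30.4375


def split_by_sct(ledger: pd.DataFrame, follow_ups: pd.DataFrame,
                 sct: pd.DataFrame) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Partition (ledger, follow_ups) into ``sct`` and ``non_sct`` strata."""
    sct_ids = set(sct.loc[sct["sct"], "patient_id"])
    out = {}
    for name, keep in (("sct", True), ("non_sct", False)):
        mask_l = ledger["patient_id"].isin(sct_ids) == keep
        mask_f = follow_ups["patient_id"].isin(sct_ids) == keep
        out[name] = (ledger.loc[mask_l], follow_ups.loc[mask_f])
    return out
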