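"""Events-of-interest hospitalisation accounting.

A stay counts as one event when its primary diagnosis matches the configured
event-of-interest code list; diagnoses appearing only as related/associated
never count.  Costs are reported as a share of all hospitalisation cost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mmlot.config import CodeLists, CostParams
from mmlot.cost_engine.rates import person_years, pppy
from mmlot.cost_engine.tables import assign_lot_numbers


def aoe_hospitalisations(stays: pd.DataFrame,
                         follow_ups: pd.DataFrame,
                         code_lists: CodeLists | None = None,
                         sct: pd.DataFrame | None = None,
                         lots: pd.DataFrame | None = None,
                         cost_params: CostParams | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return ``(events, summary)``.

    ``events`` lists qualifying stays (patient, date, code, cost).
    ``summary`` has one row per stratum (overall, first_year, sct, non_sct,
    and lot1..lot5+ when ``lots`` is given) with the population share of
    patients experiencing at least one event, the event rate PPPY, and the
    event-stay cost as a share of all hospitalisation cost in the stratum.
    """
    code_lists = code_lists or CodeLists()
    cost_params = cost_params or CostParams()

    fu = follow_ups.set_index("patient_id")
    in_cohort = stays["patient_id"].isin(fu.index)
    stays = stays.loc[in_cohort].copy()
    idx = stays["patient_id"].map(fu["index_date"])
    end = stays["patient_id"].map(fu["end_date"])
    stays = stays.loc[(stays["admit_date"] >= idx) & (stays["admit_date"] <= end)]

    primary = stays["primary_dx"].fillna("").astype(str)
    hit = pd.Series(False, index=stays.index)
    for p in code_lists.aoe_primary_prefixes:
        hit |= primary.str.startswith(p)

    events = stays.loc[hit, ["patient_id", "admit_date", "primary_dx",
                             "cost_eur"]].rename(
        columns={"admit_date": "date", "primary_dx": "code"}).reset_index(drop=True)

    fy_cut = stays["patient_id"].map(fu["index_date"]) + pd.Timedelta(days=365)
    first_year_mask = stays["admit_date"] <= fy_cut

    lot_numbers = None
    if lots is not None and len(lots):
        lot_numbers = assign_lot_numbers(stays, lots, cost_params.between_lot_policy,
                                         date_col="admit_date")

    def summarise(name, stay_mask, fu_sub):
        sub = stays.loc[stay_mask]
        sub_hit = hit.loc[sub.index]
        n_events = int(sub_hit.sum())
        event_patients = sub.loc[sub_hit, "patient_id"].nunique()
        n = len(fu_sub)
        hosp_cost = float(sub["cost_eur"].sum())
        aoe_cost = float(sub.loc[sub_hit, "cost_eur"].sum())
        years = person_years(fu_sub)
        return {
            "stratum": name,
            "n_patients": int(n),
            "n_events": n_events,
            "patients_with_event": int(event_patients),
            "pct_patients_with_event": 100.0 * event_patients / n if n else np.nan,
            "events_pppy": pppy(n_events, years),
            "aoe_cost_eur": aoe_cost,
            "hospitalisation_cost_eur": hosp_cost,
            "cost_share_pct": 100.0 * aoe_cost / hosp_cost if hosp_cost else np.nan,
        }

    all_mask = pd.Series(True, index=stays.index)
    rows = [summarise("overall", all_mask, follow_ups),
            summarise("first_year", first_year_mask, follow_ups)]
    if sct is not None and len(sct):
        sct_ids = set(sct.loc[sct["sct"], "patient_id"])
        rows.append(summarise("sct", stays["patient_id"].isin(sct_ids),
                              follow_ups.loc[follow_ups["patient_id"].isin(sct_ids)]))
        rows.append(summarise("non_sct", ~stays["patient_id"].isin(sct_ids),
                              follow_ups.loc[~follow_ups["patient_id"].isin(sct_ids)]))
    if lot_numbers is not None:
        max_lots = lots.groupby("patient_id")["lot_number"].max()
        for line in (1, 2, 3, 4):
            ids = max_lots.index[max_lots >= line]
            rows.append(summarise(
                f"lot{line}", lot_numbers == line,
                follow_ups.loc[follow_ups["patient_id"].isin(ids)]))
        ids = max_lots.index[max_lots >= 5]
        rows.append(summarise("lot5+", lot_numbers >= 5,
                              follow_ups.loc[follow_ups["patient_id"].isin(ids)]))
    return events, pd.DataFrame(rows)
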