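"""Cost ledger construction and price annualisation.

The ledger is one row per dated cost item across the three cost-bearing
claims tables, mapped to a single category each:

* hospital stays -> ``hospitalisation_excl_chemo`` / ``chemo_session`` /
  ``home_hospitalisation`` / ``rehab`` / ``emergency`` (by stay type);
* drug dispensings -> ``*_drug`` (by setting class);
* outpatient cost items -> their own category.

Stay attributes needed later for attribution (diagnoses, discharge date) are
carried along so the attribution passes work from the ledger alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mmlot.config import ConfigError, CostParams

STAY_CATEGORY = {
    "mco_complete": "hospitalisation_excl_chemo",
    "chemo_session": "chemo_session",
    "home": "home_hospitalisation",
    "rehab": "rehab",
    "emergency": "emergency",
}

DRUG_CATEGORY = {
    "high_cost": "high_cost_drug",
    "temporary_authorised": "temporary_authorised_drug",
    "retrocession": "retrocession_drug",
    "community": "community_drug",
}

HOSPITAL_CATEGORIES = tuple(STAY_CATEGORY.values())
DRUG_CATEGORIES = tuple(DRUG_CATEGORY.values())

LEDGER_COLUMNS = [
    "patient_id", "date", "category", "cost_eur_2019", "source_table",
    "source_row", "atc_code", "stay_type", "primary_dx", "related_dx",
    "associated_dx", "discharge_date", "days",
]


def annualise(costs: pd.Series, dates: pd.Series,
              price_index: dict[int, float] | None = None) -> pd.Series:
    """Bring raw euro costs to 2019 prices: ``cost * index[year(date)]``.

    ``price_index=None`` is the identity index.  An explicit index missing a
    claim year is a configuration error; negative costs are rejected.
    """
    if (costs < 0).any():
        raise ValueError("negative cost in input")
    if price_index is None:
        return costs.astype(float)
    years = pd.DatetimeIndex(dates).year
    missing = sorted(set(years) - set(price_index))
    if missing:
        raise ConfigError(f"price index missing year(s): {missing}")
    factors = np.array([price_index[y] for y in years], dtype=float)
    return costs.astype(float).to_numpy() * factors


def build_ledger(tables: dict[str, pd.DataFrame],
                 cost_params: CostParams | None = None) -> pd.DataFrame:
    """Assemble the per-item cost ledger from stays, dispensings, cost items."""
    cost_params = cost_params or CostParams()
    idx = cost_params.price_index
    pieces = []

    stays = tables.get("stays")
    if stays is not None and len(stays):
        piece = pd.DataFrame({
            "patient_id": stays["patient_id"],
            "date": stays["admit_date"],
            "category": stays["stay_type"].map(STAY_CATEGORY),
            "cost_eur_2019": annualise(stays["cost_eur"], stays["admit_date"], idx),
            "source_table": "stays",
            "source_row": stays.index,
            "atc_code": None,
            "stay_type": stays["stay_type"],
            "primary_dx": stays["primary_dx"],
            "related_dx": stays["related_dx"],
            "associated_dx": stays["associated_dx"],
            "discharge_date": stays["discharge_date"],
            "days": (stays["discharge_date"] - stays["admit_date"]).dt.days + 1,
        })
        pieces.append(piece)

    disp = tables.get("dispensings")
    if disp is not None and len(disp):
        piece = pd.DataFrame({
            "patient_id": disp["patient_id"],
            "date": disp["dispense_date"],
            "category": disp["setting_class"].map(DRUG_CATEGORY),
            "cost_eur_2019": annualise(disp["cost_eur"], disp["dispense_date"], idx),
            "source_table": "dispensings",
            "source_row": disp.index,
            "atc_code": disp["atc_code"],
            "stay_type": None, "primary_dx": None, "related_dx": None,
            "associated_dx": None, "discharge_date": pd.NaT, "days": None,
        })
        pieces.append(piece)

    items = tables.get("cost_items")
    if items is not None and len(items):
        piece = pd.DataFrame({
            "patient_id": items["patient_id"],
            "date": items["date"],
            "category": items["category"],
            "cost_eur_2019": annualise(items["cost_eur"], items["date"], idx),
            "source_table": "cost_items",
            "source_row": items.index,
            "atc_code": None, "stay_type": None, "primary_dx": None,
            "related_dx": None, "associated_dx": None, "discharge_date": pd.NaT,
            "days": items["days"],
        })
        pieces.append(piece)

    if not pieces:
        return pd.DataFrame(columns=LEDGER_COLUMNS)
    object_cols = ("atc_code", "stay_type", "primary_dx", "related_dx",
                   "associated_dx")
    for piece in pieces:
        for col in object_cols:
            piece[col] = piece[col].astype(object)
        piece["discharge_date"] = pd.to_datetime(piece["discharge_date"])
        piece["days"] = pd.to_numeric(piece["days"], errors="coerce")
    out = pd.concat(pieces, ignore_index=True)[LEDGER_COLUMNS]
    out = out.sort_values(["patient_id", "date", "category", "source_table",
                           "source_row"], kind="stable").reset_index(drop=True)
    return out


def clip_to_follow_up(ledger: pd.DataFrame, follow_ups: pd.DataFrame) -> pd.DataFrame:
    """Keep ledger rows dated inside each patient's follow-up interval."""
    fu = follow_ups.set_index("patient_id")
    index_dates = ledger["patient_id"].map(fu["index_date"])
    end_dates = ledger["patient_id"].map(fu["end_date"])
    mask = index_dates.notna() & (ledger["date"] >= index_dates) & (
        ledger["date"] <= end_dates)
    return ledger.loc[mask].reset_index(drop=True)
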