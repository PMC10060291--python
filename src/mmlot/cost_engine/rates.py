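"""Person-time denominators and PPPY/PPPM rates.

Person-years use 365.25-day years; person-months use 30.4375-day months, so
``pppm * 12 == pppy`` identically for matching numerators and denominators.
Every cohort member contributes person-time regardless of category use.
"""

from __future__ import annotations

import math

import pandas as pd

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375


def follow_up_days(follow_ups: pd.DataFrame) -> pd.Series:
    return (follow_ups["end_date"] - follow_ups["index_date"]).dt.days


def person_years(follow_ups: pd.DataFrame) -> float:
    """Total person-years over the stratum, non-users included."""
    return float(follow_up_days(follow_ups).sum()) / DAYS_PER_YEAR


def person_months(follow_ups: pd.DataFrame) -> float:
    return float(follow_up_days(follow_ups).sum()) / DAYS_PER_MONTH


def first_year_person_months(follow_ups: pd.DataFrame) -> float:
    """Observation months inside [index, index + 365 d], truncated at end."""
    days = follow_up_days(follow_ups).clip(upper=365)
    return float(days.sum()) / DAYS_PER_MONTH


def pppy(cost_sum: float, years: float) -> float:
    """Rate per person-year; NaN when the denominator is empty."""
    if years <= 0:
        return math.nan
    return cost_sum / years


def pppm(cost_sum: float, months: float) -> float:
    """Rate per person-month; NaN when the denominator is empty."""
    if months <= 0:
        return math.nan
    return cost_sum / months


def clip_first_year(ledger: pd.DataFrame, follow_ups: pd.DataFrame) -> pd.DataFrame:
    """Ledger rows dated within one year of each patient's index date."""
    fu = follow_ups.set_index("patient_id")
    index_dates = ledger["patient_id"].map(fu["index_date"])
    cutoff = index_dates + pd.Timedelta(days=365)
    mask = index_dates.notna() & (ledger["date"] >= index_dates) & (
        ledger["date"] <= cutoff)
    return ledger.loc[mask]
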