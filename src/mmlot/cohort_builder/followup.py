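"""Follow-up interval determination.

Follow-up runs from the index date to the earliest of: death, the start of
the first >= 12-month claim-free gap (classified ``disenrollment`` when a
coverage-termination record falls inside the gap year, ``lost_to_follow_up``
otherwise), or the end of the observation period.  Months are reported as
days / 30.4375 (calendar-mean month).
"""

from __future__ import annotations

import pandas as pd

DAYS_PER_MONTH = 30.4375


def collect_claim_dates(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """All dated claims as one (patient_id, date) frame, any table."""
    pieces = []
    spec = [("dispensings", "dispense_date"), ("stays", "admit_date"),
            ("stays", "discharge_date"), ("cost_items", "date"),
            ("diagnoses", "date")]
    for table, col in spec:
        if table in tables and len(tables[table]):
            df = tables[table]
            pieces.append(pd.DataFrame({"patient_id": df["patient_id"],
                                        "date": df[col]}))
    if not pieces:
        return pd.DataFrame({"patient_id": pd.Series(dtype=object),
                             "date": pd.Series(dtype="datetime64[ns]")})
    out = pd.concat(pieces, ignore_index=True).dropna(subset=["date"])
    return out


def determine_follow_up(claim_dates: pd.DataFrame,
                        patients: pd.DataFrame,
                        index_dates: pd.DataFrame,
                        study_end,
                        gap_days: int = 365) -> pd.DataFrame:
    """Per-patient follow-up end date, reason, and months.

    ``claim_dates`` is the output of :func:`collect_claim_dates`;
    ``index_dates`` needs columns ``patient_id`` and ``index_date``.
    """
    study_end = pd.Timestamp(study_end)
    pat = patients.set_index("patient_id")
    dates_by_pid = dict(tuple(claim_dates.groupby("patient_id")["date"]))

    rows = []
    for rec in index_dates.sort_values("patient_id").itertuples(index=False):
        pid, index = rec.patient_id, pd.Timestamp(rec.index_date)
        death = None
        coverage_end = None
        if pid in pat.index:
            d = pat.loc[pid, "death_date"]
            death = None if pd.isna(d) else pd.Timestamp(d)
            c = pat.loc[pid, "coverage_end_date"]
            coverage_end = None if pd.isna(c) else pd.Timestamp(c)
        if death is not None and death > study_end:
            death = None

        dates = dates_by_pid.get(pid)
        if dates is not None:
            dates = dates[(dates >= index) & (dates <= study_end)]
        claim_list = sorted(set([index] + (list(dates) if dates is not None else [])))

        gap_start = None
        horizon = death if death is not None else study_end
        for prev, nxt in zip(claim_list, claim_list[1:] + [None]):
            free = ((nxt - prev).days if nxt is not None
                    else (study_end - prev).days + 1)
            if free <= gap_days:
                continue
            if death is not None and (death - prev).days <= gap_days:
                continue  # the gap year contains a registered death
            if (study_end - prev).days < gap_days:
                continue  # gap not observable before the study ends
            gap_start = prev
            break
        del horizon

        candidates = [(study_end, "end_of_observation")]
        if gap_start is not None:
            reason = "lost_to_follow_up"
            if coverage_end is not None and gap_start < coverage_end <= (
                    gap_start + pd.Timedelta(days=gap_days)):
                reason = "disenrollment"
            candidates.append((gap_start, reason))
        if death is not None:
            candidates.append((death, "death"))
        # earliest end wins; death dominates ties
        priority = {"death": 0, "disenrollment": 1, "lost_to_follow_up": 2,
                    "end_of_observation": 3}
        end, reason = min(candidates, key=lambda c: (c[0], priority[c[1]]))
        end = max(end, index)
        rows.append({"patient_id": pid, "index_date": index, "end_date": end,
                     "end_reason": reason,
                     "months": (end - index).days / DAYS_PER_MONTH})
    return pd.DataFrame(rows, columns=["patient_id", "index_date", "end_date",
                                       "end_reason", "months"])
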