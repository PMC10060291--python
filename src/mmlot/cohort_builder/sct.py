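"""Stem-cell transplant detection from stay DRG codes or procedure codes."""

from __future__ import annotations

import pandas as pd

from mmlot.config import CodeLists, ConfigError


def detect_sct(stays: pd.DataFrame,
               cost_items: pd.DataFrame,
               follow_ups: pd.DataFrame,
               code_lists: CodeLists | None = None) -> pd.DataFrame:
    """Per-patient SCT status, first transplant date and graft type.

    A patient is SCT-positive when, during follow-up, any hospital stay
    carries a configured transplant DRG code **or** any procedure claim
    (``cost_items`` rows of category ``medical_procedure``) carries a
    configured CCAM code.  Graft type comes from the code subclass of the
    earliest matching record (DRG breaking date ties).
    """
    code_lists = code_lists or CodeLists()
    if not code_lists.sct_drg_codes and not code_lists.sct_ccam_codes:
        raise ConfigError("SCT detection requires at least one DRG or CCAM code")

    hits = []
    if len(stays):
        drg = stays.loc[stays["drg_code"].isin(code_lists.sct_drg_codes.keys())]
        for rec in drg.itertuples(index=False):
            hits.append((rec.patient_id, rec.admit_date, 0,
                         code_lists.sct_drg_codes[rec.drg_code]))
    if len(cost_items):
        proc = cost_items.loc[
            (cost_items["category"] == "medical_procedure")
            & cost_items["code"].isin(code_lists.sct_ccam_codes.keys())]
        for rec in proc.itertuples(index=False):
            hits.append((rec.patient_id, rec.date, 1,
                         code_lists.sct_ccam_codes[rec.code]))

    hit_df = pd.DataFrame(hits, columns=["patient_id", "date", "tie", "graft_type"])
    out_rows = []
    for rec in follow_ups.sort_values("patient_id").itertuples(index=False):
        pid = rec.patient_id
        mine = hit_df.loc[(hit_df["patient_id"] == pid)
                          & (hit_df["date"] >= rec.index_date)
                          & (hit_df["date"] <= rec.end_date)]
        if len(mine):
            best = mine.sort_values(["date", "tie"]).iloc[0]
            out_rows.append({"patient_id": pid, "sct": True,
                             "sct_date": best["date"],
                             "graft_type": best["graft_type"]})
        else:
            out_rows.append({"patient_id": pid, "sct": False,
                             "sct_date": pd.NaT, "graft_type": None})
    return pd.DataFrame(out_rows, columns=["patient_id", "sct", "sct_date",
                                           "graft_type"])
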