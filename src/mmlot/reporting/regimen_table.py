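"""Per-line regimen frequency table (figure-shaped output)."""

from __future__ import annotations

import pandas as pd

from mmlot.reporting.format import pct

_LINES = (1, 2, 3, 4, "5+")


def _line_mask(lots: pd.DataFrame, line) -> pd.Series:
    if isinstance(line, str) and line.endswith("+"):
        return lots["lot_number"] >= int(line[:-1])
    return lots["lot_number"] == int(line)


def render_regimen_figure(lots: pd.DataFrame,
                          sct: pd.DataFrame | None = None,
                          lines=_LINES) -> pd.DataFrame:
    """Regimen-label frequencies per line and stratum.

    Output columns: ``line``, ``stratum``, ``regimen_label``, ``n``, ``pct``
    (share of the line's patients in the stratum, one decimal) plus one
    ``distinct_regimens`` row per line/stratum counting distinct raw drug
    sets observed at that line.
    """
    if "regimen_label" not in lots.columns:
        raise ValueError("lots must carry regimen_label (run label_lots)")
    sct_ids = set(sct.loc[sct["sct"], "patient_id"]) if sct is not None else set()
    strata = {"total": pd.Series(True, index=lots.index)}
    if sct is not None:
        in_sct = lots["patient_id"].isin(sct_ids)
        strata = {"sct": in_sct, "non_sct": ~in_sct, "total": strata["total"]}

    rows = []
    for line in lines:
        at_line = _line_mask(lots, line)
        for stratum, mask in strata.items():
            sub = lots.loc[at_line & mask]
            n_patients = sub["patient_id"].nunique()
            counts = (sub.groupby("regimen_label")["patient_id"].nunique()
                      .sort_values(ascending=False))
            for label, n in counts.items():
                rows.append({"line": str(line), "stratum": stratum,
                             "regimen_label": label, "n": int(n),
                             "pct": pct(n, n_patients)})
            rows.append({"line": str(line), "stratum": stratum,
                         "regimen_label": "distinct_regimens",
                         "n": int(sub["regimen"].nunique()), "pct": None})
    return pd.DataFrame(rows, columns=["line", "stratum", "regimen_label",
                                       "n", "pct"])
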