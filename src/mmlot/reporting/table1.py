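"""Baseline characteristics and patient disposition table.

The output is tidy (``section``, ``row``, ``stratum``, ``n``, ``pct``,
``value``) so it can be pivoted to the printed layout; percentages are
computed against the stratum N through the shared rendering helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mmlot.reporting.format import pct, round_half_up

AGE_BANDS = (("18-30", 18, 30), ("31-50", 31, 50), ("51-70", 51, 70),
             (">70", 71, 200))
CHARLSON_CLASSES = (("1-2", 1, 2), ("3-4", 3, 4), (">=5", 5, 99))
LOT_COUNT_ROWS = ("undetermined", "1", "2", "3", "4", "5+")
END_REASON_ROWS = ("death", "disenrollment", "lost_to_follow_up",
                   "end_of_observation")


def distribution_rows(counts: dict[str, int], n: int,
                      order=None) -> list[dict]:
    """Count/percentage rows for a categorical distribution over a stratum.

    This is the single renderer used for every count-(%) block in the
    baseline table; percentages are ``100 * count / n`` at one decimal.
    """
    order = list(order) if order is not None else list(counts)
    return [{"row": label, "n": int(counts.get(label, 0)),
             "pct": pct(counts.get(label, 0), n)} for label in order]


def summary_rows(values: pd.Series) -> list[dict]:
    """Mean/SD/median/range/IQR rows for a continuous variable."""
    v = values.dropna().to_numpy(dtype=float)
    if not len(v):
        return [{"row": name, "value": np.nan}
                for name in ("mean", "sd", "median", "min", "max", "iqr")]
    q1, q3 = np.percentile(v, [25, 75])
    return [
        {"row": "mean", "value": round_half_up(float(np.mean(v)), 1)},
        {"row": "sd", "value": round_half_up(float(np.std(v, ddof=1)) if len(v) > 1
                                             else 0.0, 2)},
        {"row": "median", "value": round_half_up(float(np.median(v)), 1)},
        {"row": "min", "value": float(np.min(v))},
        {"row": "max", "value": float(np.max(v))},
        {"row": "iqr", "value": round_half_up(float(q3 - q1), 1)},
    ]


def _banded_counts(values: pd.Series, bands) -> dict[str, int]:
    out = {}
    for label, lo, hi in bands:
        out[label] = int(((values >= lo) & (values <= hi)).sum())
    return out


def render_table1(cohort: pd.DataFrame,
                  follow_ups: pd.DataFrame,
                  lot_counts: pd.DataFrame,
                  charlson: pd.DataFrame,
                  sct: pd.DataFrame) -> pd.DataFrame:
    """Assemble the baseline table across SCT / non-SCT / total strata."""
    df = cohort.merge(follow_ups[["patient_id", "months", "end_reason"]],
                      on="patient_id", how="left")
    df = df.merge(lot_counts, on="patient_id", how="left")
    df = df.merge(charlson[["patient_id", "score"]], on="patient_id", how="left")
    df = df.merge(sct[["patient_id", "sct"]], on="patient_id", how="left")
    df["sct"] = df["sct"].fillna(False).astype(bool)

    strata = {"sct": df.loc[df["sct"]], "non_sct": df.loc[~df["sct"]],
              "total": df}
    rows = []

    def emit(section, stratum, items):
        for item in items:
            rows.append({"section": section, "stratum": stratum, **item})

    for stratum, sub in strata.items():
        n = len(sub)
        emit("population", stratum, [{"row": "N", "n": n, "pct": pct(n, len(df))}])
        emit("age", stratum, summary_rows(sub["age_at_index"]))
        emit("age_band", stratum, distribution_rows(
            _banded_counts(sub["age_at_index"], AGE_BANDS), n,
            order=[b[0] for b in AGE_BANDS]))
        emit("sex", stratum, distribution_rows(
            {"M": int((sub["sex"] == "M").sum()),
             "F": int((sub["sex"] == "F").sum())}, n, order=("M", "F")))
        emit("charlson", stratum, summary_rows(sub["score"]))
        emit("charlson_class", stratum, distribution_rows(
            _banded_counts(sub["score"], CHARLSON_CLASSES), n,
            order=[c[0] for c in CHARLSON_CLASSES]))
        lot_labels = sub["n_lots"].map(
            lambda k: "undetermined" if k == 0 else ("5+" if k >= 5 else str(int(k))))
        emit("n_lots", stratum, distribution_rows(
            lot_labels.value_counts().to_dict(), n, order=LOT_COUNT_ROWS))
        emit("follow_up_months", stratum, summary_rows(sub["months"]))
        emit("end_reason", stratum, distribution_rows(
            sub["end_reason"].value_counts().to_dict(), n, order=END_REASON_ROWS))

    out = pd.DataFrame(rows, columns=["section", "row", "stratum", "n", "pct",
                                      "value"])
    return out
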