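"""Attrition waterfall rendering."""

from __future__ import annotations

import pandas as pd

from mmlot.reporting.format import pct


def attrition_waterfall(initial: tuple[str, int],
                        exclusions: list[tuple[str, int]]) -> pd.DataFrame:
    """Counts remaining after each exclusion, with percentages of the start.

    ``initial`` is ``(stage_name, n)``; each exclusion is ``(reason,
    n_excluded)`` applied in order.  ``pct_of_initial`` gives the share of
    the starting population each exclusion removed, at one decimal.
    """
    name, n = initial
    rows = [{"stage": name, "excluded": 0, "remaining": n,
             "pct_of_initial": pct(0, n)}]
    remaining = n
    for reason, excluded in exclusions:
        if excluded < 0 or excluded > remaining:
            raise ValueError(f"exclusion {reason!r} removes {excluded} of {remaining}")
        remaining -= excluded
        rows.append({"stage": reason, "excluded": int(excluded),
                     "remaining": int(remaining),
                     "pct_of_initial": pct(excluded, n)})
    return pd.DataFrame(rows, columns=["stage", "excluded", "remaining",
                                       "pct_of_initial"])


def exclusion_counts(exclusion_log: pd.DataFrame, order=None) -> list[tuple[str, int]]:
    """Collapse an exclusion log (patient_id, rule) into ordered counts."""
    counts = exclusion_log.groupby("rule")["patient_id"].nunique()
    if order is None:
        order = sorted(counts.index)
    return [(rule, int(counts.get(rule, 0))) for rule in order]
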