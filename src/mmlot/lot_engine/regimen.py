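"""Backbone-based regimen labelling."""

from __future__ import annotations

from typing import Iterable

import pandas as pd

DEFAULT_PRECEDENCE = (
    "daratumumab", "carfilzomib", "ixazomib", "pomalidomide",
    "bortezomib", "lenalidomide", "thalidomide", "bendamustine",
    "melphalan", "cyclophosphamide",
)


def classify_regimen(regimen: Iterable[str] | str,
                     precedence: Iterable[str] = DEFAULT_PRECEDENCE) -> str:
    """Label a drug set by the highest-precedence backbone it contains.

    ``regimen`` may be a ``+``-joined string (the lots-table encoding) or any
    iterable of drug names.  Drug sets containing no listed backbone fall
    back to ``"other"``.
    """
    if isinstance(regimen, str):
        drugs = set(regimen.split("+")) if regimen else set()
    else:
        drugs = set(regimen)
    if not drugs:
        raise ValueError("regimen must be non-empty")
    for backbone in precedence:
        if backbone in drugs:
            return f"{backbone}-based"
    return "other"


def label_lots(lots: pd.DataFrame,
               precedence: Iterable[str] = DEFAULT_PRECEDENCE) -> pd.DataFrame:
    """Return ``lots`` with a ``regimen_label`` column appended."""
    out = lots.copy()
    precedence = tuple(precedence)
    out["regimen_label"] = [classify_regimen(r, precedence) for r in out["regimen"]]
    return out
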