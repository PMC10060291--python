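"""Charlson comorbidity scoring from ICD-10 claims records.

The default weight map is a claims-adapted ICD-10 mapping of the classic
Charlson conditions (longest-prefix matching, original weights).  Conditions
are counted once each over the records dated in the year up to and including
the index date; within a severity pair (e.g., malignancy vs metastatic
disease) only the more severe condition contributes.  The cohort's own
diagnosis guarantees the malignancy weight of 2, so the minimum score is 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class CharlsonCondition:
    name: str
    weight: int
    prefixes: tuple[str, ...]
    supersedes: str | None = None  # the milder condition this one replaces


DEFAULT_WEIGHT_MAP: tuple[CharlsonCondition, ...] = (
    CharlsonCondition("myocardial_infarction", 1, ("I21", "I22", "I25.2")),
    CharlsonCondition("congestive_heart_failure", 1, ("I50", "I11.0", "I42", "I43")),
    CharlsonCondition("peripheral_vascular_disease", 1, ("I70", "I71", "I73")),
    CharlsonCondition("cerebrovascular_disease", 1,
                      ("G45", "G46", "I60", "I61", "I62", "I63", "I64",
                       "I65", "I66", "I67", "I68", "I69")),
    CharlsonCondition("dementia", 1, ("F00", "F01", "F02", "F03", "G30")),
    CharlsonCondition("chronic_pulmonary_disease", 1,
                      tuple(f"J{i}" for i in range(40, 48))
                      + tuple(f"J{i}" for i in range(60, 68))),
    CharlsonCondition("rheumatic_disease", 1, ("M05", "M06", "M32", "M33", "M34")),
    CharlsonCondition("peptic_ulcer_disease", 1, ("K25", "K26", "K27", "K28")),
    CharlsonCondition("mild_liver_disease", 1, ("B18", "K70", "K73", "K74")),
    CharlsonCondition("diabetes", 1, ("E10", "E11", "E12", "E13", "E14")),
    CharlsonCondition("diabetes_with_complications", 2,
                      tuple(f"E1{i}.{j}" for i in range(0, 5) for j in range(2, 6)),
                      supersedes="diabetes"),
    CharlsonCondition("hemiplegia", 2, ("G81", "G82")),
    CharlsonCondition("renal_disease", 2, ("N18", "N19", "I12.0", "I13.1")),
    CharlsonCondition("malignancy", 2,
                      tuple(f"C{i:02d}" for i in range(0, 77))
                      + tuple(f"C{i}" for i in range(81, 98))),
    CharlsonCondition("severe_liver_disease", 3, ("I85", "K70.4", "K72", "K76.6"),
                      supersedes="mild_liver_disease"),
    CharlsonCondition("metastatic_solid_tumour", 6, ("C77", "C78", "C79", "C80"),
                      supersedes="malignancy"),
    CharlsonCondition("aids", 6, ("B20", "B21", "B22", "B24")),
)


def _condition_for(code: str, weight_map) -> CharlsonCondition | None:
    best, best_len = None, -1
    for cond in weight_map:
        for prefix in cond.prefixes:
            if code.startswith(prefix) and len(prefix) > best_len:
                best, best_len = cond, len(prefix)
    return best


def charlson_score(diagnoses: pd.DataFrame,
                   index_dates: pd.DataFrame,
                   weight_map: tuple[CharlsonCondition, ...] = DEFAULT_WEIGHT_MAP,
                   lookback_days: int = 365) -> pd.DataFrame:
    """Score each indexed patient; returns patient_id, score, conditions.

    ``conditions`` is a ``;``-joined ``name:weight`` listing of the distinct
    contributing conditions (post-hierarchy).
    """
    by_name = {c.name: c for c in weight_map}
    diag_by_pid = dict(tuple(diagnoses.groupby("patient_id")))

    rows = []
    for rec in index_dates.sort_values("patient_id").itertuples(index=False):
        pid, index = rec.patient_id, pd.Timestamp(rec.index_date)
        lo = index - pd.Timedelta(days=lookback_days)
        found: set[str] = set()
        mine = diag_by_pid.get(pid)
        if mine is not None:
            window = mine.loc[(mine["date"] >= lo) & (mine["date"] <= index)]
            for code in window["icd10_code"]:
                cond = _condition_for(str(code), weight_map)
                if cond is not None:
                    found.add(cond.name)
        # severity hierarchy: drop a condition superseded by a present one
        for name in list(found):
            superseded = by_name[name].supersedes
            if superseded is not None and superseded in found:
                found.discard(superseded)
        score = sum(by_name[n].weight for n in found)
        conditions = ";".join(f"{n}:{by_name[n].weight}" for n in sorted(found))
        rows.append({"patient_id": pid, "score": score, "conditions": conditions})
    return pd.DataFrame(rows, columns=["patient_id", "score", "conditions"])
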