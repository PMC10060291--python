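"""Segmentation of per-drug episodes into numbered lines of therapy.

Rules, in the order they are tested for every episode start ``s`` against the
open line (started ``t0``, maximal exposure end ``E``):

* **regimen window** — episodes starting within ``t0 + regimen_window_days``
  (inclusive) join the line's regimen, whatever the drug;
* **discontinuation gap** — if ``s - E >= gap_days`` the line ended at ``E``
  (the date the grace period ended) and ``s`` opens the next line;
* **continuation** — a regimen drug re-dispensed before the gap elapses
  extends the line;
* **new drug** — any other drug ends the line the day before ``s`` and opens
  the next one, carrying over regimen drugs still in exposure at ``s``;
  unless the current regimen's exposure demonstrably continues for at least
  ``overlap_days`` past ``s`` (``E >= s + overlap_days``), in which case the
  drug is treated as a combination extension and joins the open line in
  place (disable via ``LotParams.combination_extension``).

Lines truncated by the end of follow-up, or whose closing gap is not fully
observable before it, are ``censored``.  Patients whose dispensings involve
only exempt or unobservable drugs receive zero lines (undetermined).
"""

from __future__ import annotations

import pandas as pd

from mmlot.config import LotParams
from mmlot.lot_engine.episodes import DrugEpisode

_LOT_COLUMNS = ["patient_id", "lot_number", "regimen", "start", "end",
                "end_reason", "duration_days"]


class _OpenLot:
    __slots__ = ("start", "window_end", "regimen", "episodes", "exposure_end")

    def __init__(self, start: pd.Timestamp, window: pd.Timedelta):
        self.start = start
        self.window_end = start + window
        self.regimen: set[str] = set()
        self.episodes: list[DrugEpisode] = []
        self.exposure_end: pd.Timestamp = start

    def absorb(self, ep: DrugEpisode) -> None:
        self.regimen.add(ep.drug)
        self.episodes.append(ep)
        if ep.exposure_end > self.exposure_end:
            self.exposure_end = ep.exposure_end

    def drugs_in_exposure(self, at: pd.Timestamp) -> list[DrugEpisode]:
        """Latest episode per drug whose exposure span covers ``at``."""
        latest: dict[str, DrugEpisode] = {}
        for ep in self.episodes:
            if ep.first_dispense <= at <= ep.exposure_end:
                cur = latest.get(ep.drug)
                if cur is None or ep.exposure_end > cur.exposure_end:
                    latest[ep.drug] = ep
        return list(latest.values())


def derive_lots(episodes: list[DrugEpisode],
                params: LotParams | None = None,
                follow_ups: pd.DataFrame | None = None) -> pd.DataFrame:
    """Derive numbered LOTs per patient from sorted drug episodes.

    ``follow_ups`` (columns ``patient_id``, ``end_date``) truncates streams;
    patients absent from it are treated as observed indefinitely.
    """
    params = params or LotParams()
    fu_end_by_pid: dict[str, pd.Timestamp] = {}
    if follow_ups is not None and len(follow_ups):
        fu_end_by_pid = dict(zip(follow_ups["patient_id"], follow_ups["end_date"]))

    by_patient: dict[str, list[DrugEpisode]] = {}
    for ep in episodes:
        by_patient.setdefault(ep.patient_id, []).append(ep)

    rows: list[dict] = []
    for pid in sorted(by_patient):
        fu_end = fu_end_by_pid.get(pid, pd.Timestamp.max)
        rows.extend(_derive_patient(pid, by_patient[pid], params, fu_end))
    return pd.DataFrame(rows, columns=_LOT_COLUMNS)


def _derive_patient(pid: str, eps: list[DrugEpisode], params: LotParams,
                    fu_end: pd.Timestamp) -> list[dict]:
    window = pd.Timedelta(days=params.regimen_window_days)
    gap = pd.Timedelta(days=params.gap_days)
    overlap = pd.Timedelta(days=params.overlap_days)
    one_day = pd.Timedelta(days=1)

    eps = sorted((e for e in eps if e.first_dispense <= fu_end),
                 key=lambda e: (e.first_dispense, e.drug))
    out: list[dict] = []
    lot: _OpenLot | None = None

    def close(end: pd.Timestamp, reason: str) -> None:
        end = min(end, fu_end)
        end = max(end, lot.start)
        out.append({
            "patient_id": pid, "lot_number": len(out) + 1,
            "regimen": "+".join(sorted(lot.regimen)),
            "start": lot.start, "end": end, "end_reason": reason,
            "duration_days": int((end - lot.start).days)})

    for ep in eps:
        s = ep.first_dispense
        if lot is None:
            lot = _OpenLot(s, window)
            lot.absorb(ep)
            continue
        if s <= lot.window_end:
            lot.absorb(ep)
        elif s - lot.exposure_end >= gap:
            close(lot.exposure_end, "discontinuation")
            lot = _OpenLot(s, window)
            lot.absorb(ep)
        elif ep.drug in lot.regimen:
            lot.absorb(ep)
        elif params.combination_extension and lot.exposure_end >= s + overlap:
            lot.absorb(ep)  # combination extension: regimen grows in place
        else:
            carryover = lot.drugs_in_exposure(s)
            close(min(lot.exposure_end, s - one_day), "new_drug")
            lot = _OpenLot(s, window)
            lot.absorb(ep)
            for carried in carryover:
                lot.absorb(carried)

    if lot is not None:
        if fu_end < lot.exposure_end:
            close(fu_end, "censored")
        elif fu_end - lot.exposure_end >= gap:
            close(lot.exposure_end, "discontinuation")
        else:
            close(lot.exposure_end, "censored")
    return out


def lot_counts(lots: pd.DataFrame, cohort_ids) -> pd.DataFrame:
    """Per-patient LOT count over a cohort; zero means undetermined LOT."""
    counts = lots.groupby("patient_id")["lot_number"].max() if len(lots) else {}
    out = pd.DataFrame({"patient_id": sorted(cohort_ids)})
    out["n_lots"] = out["patient_id"].map(counts).fillna(0).astype(int)
    return out
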