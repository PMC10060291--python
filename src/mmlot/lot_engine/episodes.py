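"""Per-drug exposure episodes: dispensings merged under the grace period."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from mmlot.catalogue import DrugCatalogue


@dataclass(frozen=True)
class DrugEpisode:
    patient_id: str
    drug: str
    atc_code: str
    first_dispense: pd.Timestamp
    last_dispense: pd.Timestamp
    exposure_end: pd.Timestamp  # last_dispense + grace
    grace_days: int


def build_episodes(dispensings: pd.DataFrame,
                   catalogue: DrugCatalogue | None = None,
                   include_partially_observable: bool = True,
                   include_exempt: bool = False,
                   grace_overrides: dict[str, int] | None = None,
                   ) -> list[DrugEpisode]:
    """Merge each drug's dispensings into exposure episodes.

    Only MM-indicated, observable drugs participate; partially observable
    drugs are kept by default but can be excluded, and line-exempt drugs
    (corticosteroids) are dropped unless ``include_exempt``.  Consecutive
    dispensings of one drug merge into an episode while the inter-dispense
    gap is <= the drug's grace period; ``exposure_end`` extends the last
    dispensing by the grace period.  Unknown ATC codes raise
    :class:`mmlot.catalogue.CatalogueError` listing every offending code.
    """
    catalogue = catalogue or DrugCatalogue.default()
    if grace_overrides:
        catalogue = catalogue.with_grace_overrides(grace_overrides)
    if not len(dispensings):
        return []
    catalogue.resolve(dispensings["atc_code"].unique())

    keep_codes = set()
    for spec in catalogue:
        if not spec.mm_indicated or spec.observability == "none":
            continue
        if spec.observability == "partial" and not include_partially_observable:
            continue
        if spec.lot_exempt and not include_exempt:
            continue
        keep_codes.add(spec.atc_code)

    df = dispensings.loc[dispensings["atc_code"].isin(keep_codes),
                         ["patient_id", "atc_code", "dispense_date"]]
    episodes: list[DrugEpisode] = []
    for (pid, atc), grp in df.groupby(["patient_id", "atc_code"], sort=True):
        spec = catalogue[atc]
        grace = pd.Timedelta(days=spec.grace_days)
        dates = sorted(grp["dispense_date"].unique())
        first = last = dates[0]
        for d in dates[1:]:
            if (d - last) <= grace:
                last = d
            else:
                episodes.append(DrugEpisode(pid, spec.drug_name, atc, first, last,
                                            last + grace, spec.grace_days))
                first = last = d
        episodes.append(DrugEpisode(pid, spec.drug_name, atc, first, last,
                                    last + grace, spec.grace_days))
    episodes.sort(key=lambda e: (e.patient_id, e.first_dispense, e.drug))
    return episodes


def episodes_frame(episodes: list[DrugEpisode]) -> pd.DataFrame:
    cols = ["patient_id", "drug", "atc_code", "first_dispense", "last_dispense",
            "exposure_end", "grace_days"]
    if not episodes:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([e.__dict__ for e in episodes])[cols]
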