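"""Drug catalogue: ATC-coded drug attributes driving LOT derivation and costing.

The default catalogue covers the anti-myeloma drugs observable in French
claims, grouped into four setting classes (``high_cost``,
``temporary_authorised``, ``retrocession``, ``community``).  Grace periods
default to 42 days for oral community/retrocession drugs and 49 days for
injectable hospital drugs; both are overridable per drug.  Corticosteroids
are catalogued as ``lot_exempt`` so they never open or advance a line of
therapy.  All values are configuration, not clinical guidance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Iterable, Iterator


class CatalogueError(KeyError):
    """Raised when dispensings reference ATC codes absent from the catalogue."""

    def __init__(self, codes: Iterable[str]):
        self.codes = sorted(set(codes))
        super().__init__(f"unknown ATC code(s): {', '.join(self.codes)}")


@dataclass(frozen=True)
class DrugSpec:
    atc_code: str
    drug_name: str
    mm_indicated: bool = True
    observability: str = "full"  # full | partial | none
    setting_class: str = "community"
    grace_days: int = 42
    lot_exempt: bool = False

    def __post_init__(self):
        if self.grace_days <= 0:
            raise ValueError(f"{self.drug_name}: grace_days must be positive")
        if self.observability not in ("full", "partial", "none"):
            raise ValueError(f"{self.drug_name}: bad observability {self.observability!r}")


_DEFAULT_SPECS = (
    DrugSpec("L01XG01", "bortezomib", setting_class="high_cost", grace_days=49),
    DrugSpec("L01XG02", "carfilzomib", setting_class="high_cost", grace_days=49),
    DrugSpec("L01XG03", "ixazomib", setting_class="community", grace_days=42),
    DrugSpec("L01FC01", "daratumumab", setting_class="temporary_authorised", grace_days=49),
    DrugSpec("L04AX04", "lenalidomide", setting_class="retrocession", grace_days=42),
    DrugSpec("L04AX02", "thalidomide", setting_class="retrocession", grace_days=42),
    DrugSpec("L04AX06", "pomalidomide", setting_class="retrocession", grace_days=42),
    DrugSpec("L01AA09", "bendamustine", setting_class="high_cost", grace_days=49),
    DrugSpec("L01DB01", "doxorubicine", setting_class="high_cost", grace_days=49),
    # oral forms observable in community; IV hospital use is not
    DrugSpec("L01AA03", "melphalan", observability="partial", setting_class="community"),
    DrugSpec("L01AA01", "cyclophosphamide", observability="partial", setting_class="community"),
    # widely used steroids: dispensed alongside regimens, never define a line
    DrugSpec("H02AB02", "dexamethasone", observability="partial",
             setting_class="community", lot_exempt=True),
    DrugSpec("H02AB07", "prednisone", observability="partial",
             setting_class="community", lot_exempt=True),
)


class DrugCatalogue:
    """Immutable mapping ``atc_code -> DrugSpec`` with name lookup."""

    def __init__(self, drugs: Iterable[DrugSpec]):
        self._by_atc: dict[str, DrugSpec] = {}
        self._by_name: dict[str, DrugSpec] = {}
        for spec in drugs:
            if spec.atc_code in self._by_atc:
                raise ValueError(f"duplicate ATC code {spec.atc_code}")
            self._by_atc[spec.atc_code] = spec
            self._by_name[spec.drug_name] = spec

    @classmethod
    def default(cls) -> "DrugCatalogue":
        return cls(_DEFAULT_SPECS)

    def __getitem__(self, atc_code: str) -> DrugSpec:
        try:
            return self._by_atc[atc_code]
        except KeyError:
            raise CatalogueError([atc_code]) from None

    def __contains__(self, atc_code: str) -> bool:
        return atc_code in self._by_atc

    def __iter__(self) -> Iterator[DrugSpec]:
        return iter(self._by_atc.values())

    def __len__(self) -> int:
        return len(self._by_atc)

    def by_name(self, drug_name: str) -> DrugSpec:
        try:
            return self._by_name[drug_name]
        except KeyError:
            raise CatalogueError([drug_name]) from None

    def resolve(self, atc_codes: Iterable[str]) -> None:
        """Raise :class:`CatalogueError` listing every unknown code at once."""
        unknown = {c for c in atc_codes if c not in self._by_atc}
        if unknown:
            raise CatalogueError(unknown)

    def with_grace_overrides(self, overrides: dict[str, int]) -> "DrugCatalogue":
        """New catalogue with per-drug grace periods replaced (keys: name or ATC)."""
        out = []
        for spec in self:
            days = overrides.get(spec.drug_name, overrides.get(spec.atc_code))
            out.append(replace(spec, grace_days=int(days)) if days is not None else spec)
        return DrugCatalogue(out)

    # -- CSV round trip ----------------------------------------------------

    FIELDS = ("atc_code", "drug_name", "mm_indicated", "observability",
              "setting_class", "grace_days", "lot_exempt")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(self.FIELDS)
            for s in self:
                writer.writerow([s.atc_code, s.drug_name, s.mm_indicated,
                                 s.observability, s.setting_class, s.grace_days,
                                 s.lot_exempt])

    @classmethod
    def from_csv(cls, path) -> "DrugCatalogue":
        specs = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                specs.append(DrugSpec(
                    atc_code=row["atc_code"],
                    drug_name=row["drug_name"],
                    mm_indicated=row["mm_indicated"].strip().lower() == "true",
                    observability=row["observability"],
                    setting_class=row["setting_class"],
                    grace_days=int(row["grace_days"]),
                    lot_exempt=row["lot_exempt"].strip().lower() == "true",
                ))
        return cls(specs)
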