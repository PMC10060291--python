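"""Rendering arithmetic for report tables.

These helpers are the single code path between full-precision aggregates and
the printed-precision cells (percentages to one decimal, K€/M€ to two), so
every rendered number can be recomputed from its numerator and denominator.
Rounding is half-away-from-zero, matching conventional report rounding.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 0) -> float:
    if math.isnan(value):
        return value
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage of a stratum: ``100 * n / N`` at report precision."""
    if denominator == 0:
        return math.nan
    return round_half_up(100.0 * numerator / denominator, decimals)


def share_pct(part: float, total: float, decimals: int = 1) -> float:
    """Share of a cost total, e.g. first-year hospitalisation of first-year total."""
    return pct(part, total, decimals)


def mean_per_person_keur(sum_meur: float, n: int, decimals: int = 2) -> float:
    """Mean cost per person in K€ from a stratum sum in M€."""
    if n == 0:
        return math.nan
    return round_half_up(sum_meur * 1000.0 / n, decimals)


def eur_to_keur(eur: float, decimals: int = 2) -> float:
    return round_half_up(eur / 1e3, decimals)


def eur_to_meur(eur: float, decimals: int = 2) -> float:
    return round_half_up(eur / 1e6, decimals)
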