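"""Independent brute-force oracles used to check the production algorithms.

The LOT oracle works directly on (day, drug) dispensing events — no episode
pre-merging, no shared code with the engine.  Exposure is recomputed on
demand by chaining a drug's dispensings while consecutive gaps stay within
the grace period.  Rules applied, in order, at every event:

* events within the regimen window join the open line;
* an event at least ``gap`` days after the line's exposure end closes it
  (discontinuation at the exposure end) and opens the next line;
* a regimen drug re-dispensed sooner extends the line;
* a new drug extends the line in place when the regimen's exposure runs at
  least ``overlap`` days past the event (combination extension, if enabled),
  otherwise it closes the line the day before and opens the next one,
  carrying over drugs still in exposure.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OracleLot:
    start: int
    end: int
    regimen: frozenset
    reason: str


def _run_end(day: int, drug: str, all_events: list[tuple[int, str]],
             grace: int) -> int:
    """Last day of the dispensing chain through ``day`` with gaps <= grace."""
    end = day
    for d, g in all_events:
        if g != drug or d <= end:
            continue
        if d - end <= grace:
            end = d
        elif d > end + grace:
            break
    return end


def oracle_lots(events: list[tuple[int, str]], grace: dict[str, int],
                window: int = 28, gap: int = 90, overlap: int = 40,
                combination_extension: bool = True,
                fu_end: int | None = None) -> list[OracleLot]:
    events = sorted(e for e in set(events) if fu_end is None or e[0] <= fu_end)
    lots: list[OracleLot] = []
    start = None
    regimen: set[str] = set()
    last: dict[str, int] = {}

    def exposure_end() -> int:
        return max(_run_end(last[d], d, events, grace[d]) + grace[d]
                   for d in regimen)

    def close(end: int, reason: str) -> None:
        end = end if fu_end is None else min(end, fu_end)
        lots.append(OracleLot(start, max(end, start), frozenset(regimen), reason))

    for day, drug in events:
        if start is None:
            start, regimen, last = day, {drug}, {drug: day}
            continue
        if day <= start + window:
            regimen.add(drug)
            last[drug] = day
            continue
        e = exposure_end()
        if day - e >= gap:
            close(e, "discontinuation")
            start, regimen, last = day, {drug}, {drug: day}
        elif drug in regimen:
            last[drug] = day
        elif combination_extension and e >= day + overlap:
            regimen.add(drug)
            last[drug] = day
        else:
            carry = {d: last[d] for d in regimen
                     if last[d] + grace[d] >= day}
            close(min(e, day - 1), "new_drug")
            start = day
            regimen = {drug} | set(carry)
            last = {**carry, drug: day}

    if start is not None:
        e = exposure_end()
        if fu_end is not None and fu_end < e:
            close(fu_end, "censored")
        elif fu_end is not None and fu_end - e < gap:
            close(e, "censored")
        else:
            close(e, "discontinuation")
    return lots


def km_by_hand(durations: list[float], observed: list[bool]):
    """Product-limit survival curve from first principles.

    Returns (times, survival) at each distinct event time, and the median
    (first time survival drops to <= 0.5; None when never reached).
    """
    pairs = sorted(zip(durations, observed))
    n = len(pairs)
    at_risk = n
    s = 1.0
    times, surv = [], []
    i = 0
    while i < n:
        t = pairs[i][0]
        deaths = sum(1 for d, o in pairs if d == t and o)
        censored = sum(1 for d, o in pairs if d == t and not o)
        if deaths:
            s *= (at_risk - deaths) / at_risk
            times.append(t)
            surv.append(s)
        at_risk -= deaths + censored
        i += deaths + censored
    median = None
    for t, sv in zip(times, surv):
        if sv <= 0.5 + 1e-12:
            median = t
            break
    return times, surv, median
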