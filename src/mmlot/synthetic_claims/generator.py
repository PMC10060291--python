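"""Seeded generator of claims tables with retained ground-truth labels.

Each patient is built from a latent trajectory (index date, line-of-therapy
sequence, transplant, death/censoring) and the five claims tables are emitted
from it, so downstream stages can be scored against truth.  Randomness is
drawn from one :class:`numpy.random.SeedSequence` child per patient, keyed by
``(config.seed, patient index)``: outputs are byte-identical for identical
``(config, seed)`` and stable under changes to ``n_patients``.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from mmlot.catalogue import DrugCatalogue
from mmlot.schemas import CLAIMS_TABLES, GROUND_TRUTH, write_table
from mmlot.synthetic_claims.config import CostDist, SimConfig, ViolationRates

DAY = dt.timedelta(days=1)

#: rule identifiers in cohort_builder evaluation order; truth labels use the
#: first applicable one so verdicts can be compared one-to-one
RULE_ORDER = (
    "missing_data",
    "age_over_18",
    "general_scheme",
    "insufficient_history",
    "prior_mm",
    "other_malignancy",
    "no_mm_treatment",
    "treatment_after_30d",
)

_AOE_STAY_CODES = ("J18.9", "D64.9", "A41.9", "I26.0", "B02.9", "G62.0", "M80.0")
_OTHER_STAY_CODES = ("I10", "K21.9", "M54.5", "R07.4", "S72.0")
_COMORBIDITY_CODES = ("E11.9", "J44.9", "N18.3", "I50.0", "F03")
_PRIOR_MALIGNANCY_CODES = ("C61", "C50.9", "C18.9")

_SCT_STAY_DRG = "28Z13Z"           # autologous by default
_SCT_STAY_DRG_ALLO = "28Z11Z"
_SCT_CCAM = "FEJF008"
_SCT_CCAM_ALLO = "FEJF010"


def _cost(rng: np.random.Generator, dist: CostDist) -> float:
    value = math.exp(math.log(dist.median_eur) + dist.sigma * rng.standard_normal())
    return round(float(value), 2)


def _pick(rng: np.random.Generator, options, probs):
    return options[int(rng.choice(len(options), p=probs))]


def _earlier_rule(a: str | None, b: str | None) -> str | None:
    if a is None:
        return b
    if b is None:
        return a
    return a if RULE_ORDER.index(a) <= RULE_ORDER.index(b) else b


class _Tables:
    """Row accumulators for the five claims tables."""

    def __init__(self):
        self.patients: list[dict] = []
        self.diagnoses: list[dict] = []
        self.dispensings: list[dict] = []
        self.stays: list[dict] = []
        self.cost_items: list[dict] = []


def generate_population(config: SimConfig, catalogue: DrugCatalogue | None = None,
                        ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate the five claims tables plus the ground-truth table.

    Returns ``(tables, ground_truth)`` where ``tables`` maps the table name
    (``patients``, ``diagnoses``, ``dispensings``, ``stays``, ``cost_items``)
    to a validated :class:`pandas.DataFrame`.
    """
    config = SimConfig.model_validate(config) if not isinstance(config, SimConfig) else config
    catalogue = catalogue or DrugCatalogue.default()

    acc = _Tables()
    truth_rows: list[dict] = []
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_patients)
    for i in range(config.n_patients):
        rng = np.random.default_rng(children[i])
        _generate_patient(f"P{i:06d}", rng, config, catalogue, acc, truth_rows)

    tables = {
        "patients": _frame(acc.patients, "patients"),
        "diagnoses": _frame(acc.diagnoses, "diagnoses"),
        "dispensings": _frame(acc.dispensings, "dispensings"),
        "stays": _frame(acc.stays, "stays"),
        "cost_items": _frame(acc.cost_items, "cost_items"),
    }
    ground_truth = _truth_frame(truth_rows)
    return tables, ground_truth


def _frame(rows: list[dict], name: str) -> pd.DataFrame:
    schema = CLAIMS_TABLES[name]
    if not rows:
        return schema.empty()
    df = pd.DataFrame(rows)
    for col in schema.column_names:
        if col not in df.columns:
            df[col] = None
    return schema.validate(df[list(schema.column_names)])


def _truth_frame(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return GROUND_TRUTH.empty()
    return GROUND_TRUTH.validate(pd.DataFrame(rows)[list(GROUND_TRUTH.column_names)])


def _generate_patient(pid: str, rng: np.random.Generator, config: SimConfig,
                      catalogue: DrugCatalogue, acc: _Tables, truth_rows: list[dict]):
    sct_assigned = rng.random() < config.sct_probability
    stratum = "sct" if sct_assigned else "non_sct"
    age_dist = config.age_distribution[stratum]
    age = int(np.clip(round(rng.normal(age_dist.mean, age_dist.sd)), 20, 95))
    sex = "M" if rng.random() < 0.52 else "F"

    span = (config.inclusion_end - config.inclusion_start).days
    index = config.inclusion_start + int(rng.integers(0, span + 1)) * DAY
    birth_year = index.year - age

    # death from a constant per-day hazard
    hazard_month = config.death_hazard_per_month[stratum]
    death = None
    if hazard_month > 0:
        surv_days = rng.exponential(30.4375 / hazard_month)
        candidate = index + max(1, int(surv_days)) * DAY
        if candidate <= config.study_end:
            death = candidate

    # censoring by claim gap: only simulated for patients without a death
    lost = False
    coverage_end = None
    horizon_days = (config.study_end - index).days
    if death is None and config.noise.p_lost_to_followup > 0 and horizon_days >= 600:
        if rng.random() < config.noise.p_lost_to_followup:
            lost = True
            cutoff = index + int(rng.integers(90, horizon_days - 430 + 1)) * DAY
            if rng.random() < 0.3:
                coverage_end = cutoff + int(rng.integers(1, 61)) * DAY
    fu_end = death if death is not None else config.study_end
    if lost:
        fu_end = min(fu_end, cutoff)

    acc.patients.append({
        "patient_id": pid, "birth_year": birth_year, "sex": sex,
        "general_scheme": True, "death_date": death, "coverage_end_date": coverage_end,
    })

    fail_reason: str | None = None

    # --- diagnosis confirmation records ---------------------------------
    short_followup = (fu_end - index).days < 3
    if short_followup or rng.random() < 0.3:
        # one hospital record + long-term disease registration
        _mm_stay(pid, rng, config, acc, index, fu_end)
        acc.diagnoses.append({"patient_id": pid, "icd10_code": "C90.0",
                              "date": index, "source": "long_term_disease"})
    else:
        _mm_stay(pid, rng, config, acc, index, fu_end)
        second = min(index + int(rng.integers(3, 21)) * DAY, fu_end)
        _mm_stay(pid, rng, config, acc, second, fu_end,
                 source=_pick(rng, ["hospital_primary", "hospital_related",
                                    "hospital_associated"], [0.5, 0.3, 0.2]))
        if rng.random() < 0.5:
            acc.diagnoses.append({"patient_id": pid, "icd10_code": "C90.0",
                                  "date": min(index + 10 * DAY, fu_end),
                                  "source": "long_term_disease"})

    # comorbidity history in the year before index (feeds Charlson scoring)
    if rng.random() < 0.35:
        for code in rng.choice(_COMORBIDITY_CODES, size=int(rng.integers(1, 3)),
                               replace=False):
            acc.diagnoses.append({
                "patient_id": pid, "icd10_code": str(code),
                "date": index - int(rng.integers(10, 360)) * DAY,
                "source": "hospital_associated"})

    # non-MM malignancy history noise -> truly ineligible patient
    if rng.random() < config.noise.p_other_malignancy_history:
        back = int(rng.integers(400, 1700))
        acc.diagnoses.append({
            "patient_id": pid, "icd10_code": str(rng.choice(_PRIOR_MALIGNANCY_CODES)),
            "date": index - back * DAY, "source": "hospital_primary"})
        fail_reason = _earlier_rule(fail_reason, "other_malignancy")

    # --- treatment trajectory -------------------------------------------
    n_lots = _draw_n_lots(rng, config)
    delay = int(rng.integers(0, config.treatment_delay_max_days + 1))
    first_treat = index + delay * DAY

    dispensing_rows: list[dict] = []
    true_lots: list[dict] = []
    if n_lots == 0:
        # treated, but only with drugs that never define a line
        _emit_cycles(pid, rng, config, catalogue, dispensing_rows, acc,
                     ["dexamethasone"], first_treat, n_cycles=6, fu_end=fu_end)
    else:
        t = first_treat
        for line in range(1, n_lots + 1):
            menu = config.regimen_menu.get(str(line), config.regimen_menu["default"])
            option = _pick(rng, menu, [o.prob for o in menu])
            dur_dist = config.lot_duration.get(str(line), config.lot_duration["default"])
            duration = float(np.clip(
                math.exp(math.log(dur_dist.median_days)
                         + dur_dist.sigma * rng.standard_normal()), 28, 1200))
            n_cycles = int(duration // 28) + 1
            records = _emit_cycles(pid, rng, config, catalogue, dispensing_rows, acc,
                                   option.drugs, t, n_cycles, fu_end)
            non_exempt = [d for d in option.drugs if not catalogue.by_name(d).lot_exempt]
            if non_exempt:
                max_grace = max(catalogue.by_name(d).grace_days for d in non_exempt)
                surviving = [date for drug, date in records if drug in non_exempt]
                if surviving:
                    start, last = min(surviving), max(surviving)
                    true_lots.append({
                        "drugs": sorted(non_exempt),
                        "start": start.isoformat(),
                        "end": min(last + max_grace * DAY, fu_end).isoformat(),
                    })
                exposure_end = t + 28 * (n_cycles - 1) * DAY + max_grace * DAY
            else:  # pragma: no cover - menus always hold a non-exempt drug
                exposure_end = t + 28 * n_cycles * DAY
            extra = int(rng.exponential(config.gap_extra_mean_days))
            t = exposure_end + (config.gap_between_lots_min_days + extra) * DAY
            if t > fu_end:
                break

    if dispensing_rows:
        first_disp = min(r["dispense_date"] for r in dispensing_rows)
        if (first_disp - index).days > 30:  # pragma: no cover - delay <= 21 by default
            fail_reason = _earlier_rule(fail_reason, "treatment_after_30d")
    else:
        fail_reason = _earlier_rule(fail_reason, "no_mm_treatment")
        true_lots = []

    # missing-dispensing noise drops claims rows, never the truth labels
    if config.noise.p_missing_dispensing > 0 and dispensing_rows:
        keep = rng.random(len(dispensing_rows)) >= config.noise.p_missing_dispensing
        dispensing_rows = [r for r, k in zip(dispensing_rows, keep) if k]
    acc.dispensings.extend(dispensing_rows)

    # --- stem cell transplant -------------------------------------------
    true_sct, sct_date = False, None
    if sct_assigned:
        candidate = index + int(rng.integers(60, 240)) * DAY
        if candidate + 14 * DAY <= fu_end:
            true_sct, sct_date = True, candidate
            allo = rng.random() < 0.025
            acc.stays.append({
                "patient_id": pid, "admit_date": sct_date,
                "discharge_date": sct_date + 14 * DAY, "stay_type": "mco_complete",
                "drg_code": _SCT_STAY_DRG_ALLO if allo else _SCT_STAY_DRG,
                "primary_dx": "C90.0", "related_dx": None, "associated_dx": None,
                "cost_eur": _cost(rng, config.cost_distributions["stay_sct"])})
            acc.cost_items.append({
                "patient_id": pid, "date": sct_date, "category": "medical_procedure",
                "cost_eur": _cost(rng, config.cost_distributions["medical_procedure"]),
                "days": None, "code": _SCT_CCAM_ALLO if allo else _SCT_CCAM})
            if rng.random() < 0.25:
                admit = sct_date + 14 * DAY + int(rng.integers(0, 2)) * DAY
                if admit + 20 * DAY <= fu_end:
                    acc.stays.append({
                        "patient_id": pid, "admit_date": admit,
                        "discharge_date": admit + 20 * DAY, "stay_type": "rehab",
                        "drg_code": None, "primary_dx": "Z50.1", "related_dx": None,
                        "associated_dx": None,
                        "cost_eur": _cost(rng, config.cost_distributions["stay_rehab"])})

    _emit_background(pid, rng, config, acc, index, fu_end, age)

    if death is not None:
        end_reason, true_end = "death", death
    elif lost:
        end_reason = "disenrollment" if coverage_end is not None else "lost_to_follow_up"
        true_end = _last_claim_date(acc, pid)
    else:
        end_reason, true_end = "end_of_observation", config.study_end

    truth_rows.append({
        "patient_id": pid,
        "true_index_date": index,
        "true_eligible": fail_reason is None,
        "true_fail_reason": fail_reason,
        "true_n_lots": len(true_lots),
        "true_lot_json": json.dumps(true_lots, separators=(",", ":")),
        "true_sct": true_sct,
        "true_sct_date": sct_date,
        "true_death_date": death,
        "true_followup_end": true_end,
        "true_end_reason": end_reason,
    })


def _draw_n_lots(rng, config: SimConfig) -> int:
    keys = sorted(config.n_lot_distribution)
    probs = [config.n_lot_distribution[k] for k in keys]
    drawn = _pick(rng, keys, np.asarray(probs) / sum(probs))
    if drawn == "5+":
        return 5 + min(int(rng.geometric(0.6)) - 1, 3)
    return int(drawn)


def _mm_stay(pid, rng, config: SimConfig, acc: _Tables, admit, fu_end,
             source: str = "hospital_primary"):
    discharge = min(admit + int(rng.integers(2, 9)) * DAY, fu_end)
    acc.stays.append({
        "patient_id": pid, "admit_date": admit, "discharge_date": discharge,
        "stay_type": "mco_complete", "drg_code": None,
        "primary_dx": "C90.0" if source == "hospital_primary" else "R53",
        "related_dx": "C90.0" if source == "hospital_related" else None,
        "associated_dx": "C90.0" if source == "hospital_associated" else None,
        "cost_eur": _cost(rng, config.cost_distributions["stay_mco"])})
    acc.diagnoses.append({"patient_id": pid, "icd10_code": "C90.0",
                          "date": admit, "source": source})


def _emit_cycles(pid, rng, config: SimConfig, catalogue: DrugCatalogue,
                 dispensing_rows: list[dict], acc: _Tables, drugs, start,
                 n_cycles, fu_end) -> list[tuple[str, dt.date]]:
    """Emit one claim per drug per 28-day cycle, plus linked hospital activity.

    Returns the intended (drug, date) records before any noise, truncated at
    the end of follow-up.
    """
    records = []
    for k in range(n_cycles):
        date = start + 28 * k * DAY
        if date > fu_end:
            break
        for drug in drugs:
            spec = catalogue.by_name(drug)
            records.append((drug, date))
            dispensing_rows.append({
                "patient_id": pid, "atc_code": spec.atc_code, "drug_label": drug,
                "dispense_date": date, "setting_class": spec.setting_class,
                "packs": 1,
                "cost_eur": _cost(rng, config.cost_distributions[
                    f"dispensing_{spec.setting_class}"])})
            if spec.setting_class in ("high_cost", "temporary_authorised"):
                # hospital-administered: a chemo-session stay carries the visit
                acc.stays.append({
                    "patient_id": pid, "admit_date": date, "discharge_date": date,
                    "stay_type": "chemo_session", "drg_code": None,
                    "primary_dx": "Z51.1", "related_dx": "C90.0",
                    "associated_dx": None,
                    "cost_eur": _cost(rng, config.cost_distributions["stay_chemo"])})
                if rng.random() < 0.6:
                    acc.cost_items.append({
                        "patient_id": pid, "date": date + int(rng.integers(0, 2)) * DAY,
                        "category": "transport",
                        "cost_eur": _cost(rng, config.cost_distributions["transport"]),
                        "days": None, "code": None})
                if rng.random() < 0.06:
                    sl_date = date + int(rng.integers(0, 8)) * DAY
                    if sl_date <= fu_end:
                        days = int(rng.integers(5, 30))
                        acc.cost_items.append({
                            "patient_id": pid, "date": sl_date,
                            "category": "sick_leave_invalidity",
                            "cost_eur": round(days * _cost(
                                rng, config.cost_distributions["sick_leave_invalidity"]), 2),
                            "days": days, "code": None})
    return records


def _emit_background(pid, rng, config: SimConfig, acc: _Tables, index, fu_end, age):
    """Regular non-MM claims keeping patients continuously observable."""
    fu_days = (fu_end - index).days
    cadence = int(rng.integers(25, 41))
    for off in range(cadence, fu_days + 1, cadence):
        acc.cost_items.append({
            "patient_id": pid, "date": index + off * DAY, "category": "physician_visit",
            "cost_eur": _cost(rng, config.cost_distributions["physician_visit"]),
            "days": None, "code": None})
    for off in range(45, fu_days + 1, 60):
        acc.cost_items.append({
            "patient_id": pid, "date": index + off * DAY, "category": "lab_test",
            "cost_eur": _cost(rng, config.cost_distributions["lab_test"]),
            "days": None, "code": None})
    for off in range(90, fu_days + 1, 120):
        category = "other_professional_visit" if rng.random() < 0.7 else "medical_device"
        acc.cost_items.append({
            "patient_id": pid, "date": index + off * DAY, "category": category,
            "cost_eur": _cost(rng, config.cost_distributions[category]),
            "days": None, "code": None})

    years = max(fu_days, 1) / 365.25
    for _ in range(int(rng.poisson(0.6 * years))):
        admit = index + int(rng.integers(0, fu_days + 1)) * DAY
        is_aoe = rng.random() < 0.65
        primary = str(rng.choice(_AOE_STAY_CODES if is_aoe else _OTHER_STAY_CODES))
        discharge = min(admit + int(rng.integers(3, 16)) * DAY, fu_end)
        acc.stays.append({
            "patient_id": pid, "admit_date": admit, "discharge_date": discharge,
            "stay_type": "mco_complete", "drg_code": None, "primary_dx": primary,
            "related_dx": "C90.0" if rng.random() < 0.5 else None,
            "associated_dx": None,
            "cost_eur": _cost(rng, config.cost_distributions["stay_mco"])})
    for _ in range(int(rng.poisson(0.3 * years))):
        admit = index + int(rng.integers(0, fu_days + 1)) * DAY
        acc.stays.append({
            "patient_id": pid, "admit_date": admit, "discharge_date": admit,
            "stay_type": "emergency", "drg_code": None,
            "primary_dx": str(rng.choice(_OTHER_STAY_CODES)), "related_dx": None,
            "associated_dx": None,
            "cost_eur": _cost(rng, config.cost_distributions["stay_emergency"])})
    if fu_days >= 60 and rng.random() < 0.12:
        admit = index + int(rng.integers(30, fu_days - 20)) * DAY
        acc.stays.append({
            "patient_id": pid, "admit_date": admit,
            "discharge_date": admit + int(rng.integers(5, 20)) * DAY,
            "stay_type": "home", "drg_code": None, "primary_dx": None,
            "related_dx": "C90.0" if rng.random() < 0.8 else None, "associated_dx": None,
            "cost_eur": _cost(rng, config.cost_distributions["stay_home"])})


def _last_claim_date(acc: _Tables, pid: str):
    dates = []
    dates += [r["dispense_date"] for r in acc.dispensings if r["patient_id"] == pid]
    dates += [r["admit_date"] for r in acc.stays if r["patient_id"] == pid]
    dates += [r["date"] for r in acc.cost_items if r["patient_id"] == pid]
    dates += [r["date"] for r in acc.diagnoses if r["patient_id"] == pid]
    return max(dates) if dates else None


# ---------------------------------------------------------------------------
# protocol violations


def inject_protocol_violations(tables: dict[str, pd.DataFrame],
                               ground_truth: pd.DataFrame,
                               rates: ViolationRates | None = None,
                               seed: int = 0,
                               inclusion_start=dt.date(2013, 1, 1),
                               ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Turn a slice of generated patients into known-ineligible strata.

    Patients are independently assigned at most one violation (``untreated``,
    ``late_start``, ``prior_malignancy``, ``prior_mm``) with the configured
    probabilities; claims are edited accordingly and the ground-truth verdicts
    updated so exclusion counts can be scored exactly.  Rate 0 for every
    violation returns the inputs unchanged.

    A ``prior_mm`` record must predate the inclusion window (otherwise it
    would merely move the index date earlier), so that violation is only
    realisable for patients indexed within a year of the window start;
    drawn but unrealisable cases are skipped.
    """
    rates = rates or ViolationRates()
    if all(p == 0 for _, p in rates.items):
        return tables, ground_truth

    tables = {k: v.copy() for k, v in tables.items()}
    gt = ground_truth.copy().set_index("patient_id", drop=False)
    disp = tables["dispensings"]
    diag = tables["diagnoses"]
    new_diag_rows = []

    root = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    children = root.spawn(len(gt))
    drop_mask = pd.Series(False, index=disp.index)
    for child, (pid, row) in zip(children, gt.iterrows()):
        rng = np.random.default_rng(child)
        u = rng.random()
        violation = None
        cum = 0.0
        for name, p in rates.items:
            cum += p
            if u < cum:
                violation = name
                break
        if violation is None:
            continue
        index_date = row["true_index_date"]
        mask = disp["patient_id"] == pid
        if violation == "untreated":
            drop_mask |= mask
            gt.loc[pid, ["true_n_lots", "true_lot_json"]] = [0, "[]"]
            _fail(gt, pid, "no_mm_treatment")
        elif violation == "late_start":
            if not mask.any():
                continue
            first = disp.loc[mask, "dispense_date"].min()
            target = index_date + pd.Timedelta(days=31 + int(rng.integers(0, 30)))
            delta = target - first
            disp.loc[mask, "dispense_date"] = disp.loc[mask, "dispense_date"] + delta
            fu_end = row["true_followup_end"]
            overshoot = mask & (disp["dispense_date"] > fu_end)
            drop_mask |= overshoot
            gt.loc[pid, "true_lot_json"] = _shift_lots(
                row["true_lot_json"], delta, fu_end)
            gt.loc[pid, "true_n_lots"] = len(json.loads(gt.loc[pid, "true_lot_json"]))
            if (mask & ~overshoot).any():
                _fail(gt, pid, "treatment_after_30d")
            else:  # the whole stream fell past the end of observation
                gt.loc[pid, ["true_n_lots", "true_lot_json"]] = [0, "[]"]
                _fail(gt, pid, "no_mm_treatment")
        elif violation == "prior_malignancy":
            new_diag_rows.append({
                "patient_id": pid, "icd10_code": "C18.9",
                "date": index_date - pd.Timedelta(days=730), "source": "hospital_primary"})
            _fail(gt, pid, "other_malignancy")
        elif violation == "prior_mm":
            record_date = pd.Timestamp(inclusion_start) - pd.Timedelta(days=1)
            if record_date <= index_date - pd.Timedelta(days=365):
                continue  # cannot fall in the lookback without moving the index
            new_diag_rows.append({
                "patient_id": pid, "icd10_code": "C90.0",
                "date": record_date, "source": "long_term_disease"})
            _fail(gt, pid, "prior_mm")

    tables["dispensings"] = disp.loc[~drop_mask].reset_index(drop=True)
    if new_diag_rows:
        diag = pd.concat([diag, pd.DataFrame(new_diag_rows)], ignore_index=True)
        diag = diag.sort_values(["patient_id", "date", "icd10_code"],
                                kind="stable").reset_index(drop=True)
        tables["diagnoses"] = diag
    return tables, gt.reset_index(drop=True)


def _fail(gt: pd.DataFrame, pid: str, reason: str) -> None:
    current = gt.loc[pid, "true_fail_reason"]
    current = None if pd.isna(current) else current
    gt.loc[pid, "true_fail_reason"] = _earlier_rule(current, reason)
    gt.loc[pid, "true_eligible"] = False


def _shift_lots(lot_json: str, delta: pd.Timedelta, fu_end) -> str:
    lots = json.loads(lot_json) if isinstance(lot_json, str) else []
    out = []
    for lot in lots:
        start = pd.Timestamp(lot["start"]) + delta
        end = pd.Timestamp(lot["end"]) + delta
        if start > fu_end:
            continue
        out.append({"drugs": lot["drugs"], "start": start.date().isoformat(),
                    "end": min(end, pd.Timestamp(fu_end)).date().isoformat()})
    return json.dumps(out, separators=(",", ":"))


# ---------------------------------------------------------------------------
# i/o


def write_population(tables: dict[str, pd.DataFrame], ground_truth: pd.DataFrame,
                     out_dir: str | Path) -> list[Path]:
    """Write all claims tables plus ``ground_truth.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, schema in CLAIMS_TABLES.items():
        path = out_dir / schema.name
        write_table(tables[name], path, schema)
        written.append(path)
    path = out_dir / GROUND_TRUTH.name
    write_table(ground_truth, path, GROUND_TRUTH)
    written.append(path)
    return written
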