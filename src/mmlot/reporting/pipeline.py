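"""End-to-end pipeline orchestration: simulate -> cohort -> lots -> costs -> report.

Each stage is a pure function over data frames; :func:`run_pipeline` wires
them together, writes every output table as CSV under the output directory,
and records a run manifest (config hash, seed, input digests, row counts per
stage) for reproducibility checks.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from mmlot import __version__
from mmlot.catalogue import DrugCatalogue
from mmlot.cohort_builder import (
    apply_eligibility,
    charlson_score,
    collect_claim_dates,
    confirm_mm_diagnosis,
    detect_sct,
    determine_follow_up,
    set_index_date,
)
from mmlot.cohort_builder.eligibility import RULE_ORDER
from mmlot.config import PipelineConfig
from mmlot.cost_engine import (
    aoe_hospitalisations,
    build_allcause_table,
    build_ledger,
    build_mm_admin_by_lot,
    clip_to_follow_up,
    rate_report,
    split_by_sct,
    tag_mm_related,
    tag_mm_treatment_admin,
)
from mmlot.lot_engine import (
    build_episodes,
    derive_lots,
    km_curves_frame,
    label_lots,
    lot_counts,
)
from mmlot.reporting.attrition import attrition_waterfall
from mmlot.reporting.regimen_table import render_regimen_figure
from mmlot.reporting.table1 import render_table1
from mmlot.schemas import CLAIMS_TABLES, GROUND_TRUTH, read_table, write_table
from mmlot.synthetic_claims import (
    SimConfig,
    generate_population,
    inject_protocol_violations,
    write_population,
)

logger = logging.getLogger("mmlot")


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    ground_truth: pd.DataFrame | None
    cohort: pd.DataFrame
    verdicts: pd.DataFrame
    exclusion_log: pd.DataFrame
    follow_ups: pd.DataFrame
    sct: pd.DataFrame
    charlson: pd.DataFrame
    lots: pd.DataFrame
    lot_count_table: pd.DataFrame
    outputs: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def load_claims(in_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the five claims tables, erroring with the missing file's name."""
    in_dir = Path(in_dir)
    for schema in CLAIMS_TABLES.values():
        if not (in_dir / schema.name).exists():
            raise FileNotFoundError(
                f"required input table not found: {in_dir / schema.name}")
    return {name: read_table(in_dir / schema.name, schema)
            for name, schema in CLAIMS_TABLES.items()}


def cohort_stage(tables: dict[str, pd.DataFrame], config: PipelineConfig,
                 catalogue: DrugCatalogue | None = None) -> dict:
    catalogue = catalogue or DrugCatalogue.default()
    win = config.study_window
    patients = tables["patients"]

    confirmation = confirm_mm_diagnosis(
        tables["diagnoses"], win.inclusion_start, win.inclusion_end,
        mm_prefixes=tuple(config.code_lists.mm_diagnosis_prefixes))
    # patients with no diagnosis rows at all are unconfirmed by definition
    no_diag = set(patients["patient_id"]) - set(confirmation["patient_id"])
    indexed, dropped = set_index_date(confirmation)

    verdicts = apply_eligibility(
        patients, tables["diagnoses"], tables["dispensings"], indexed,
        catalogue=catalogue, params=config.eligibility,
        code_lists=config.code_lists, history_start=win.history_start)

    exclusion_rows = [{"patient_id": pid, "rule": "diagnosis_not_confirmed",
                       "evidence": "no diagnosis records"} for pid in sorted(no_diag)]
    for rec in dropped.itertuples(index=False):
        exclusion_rows.append({"patient_id": rec.patient_id, "rule": rec.rule,
                               "evidence": ""})
    failed = verdicts.loc[~verdicts["eligible"]]
    for rec in failed.itertuples(index=False):
        exclusion_rows.append({"patient_id": rec.patient_id,
                               "rule": rec.first_failed_rule,
                               "evidence": rec.evidence})
    exclusion_log = pd.DataFrame(exclusion_rows,
                                 columns=["patient_id", "rule", "evidence"])

    eligible = verdicts.loc[verdicts["eligible"], ["patient_id", "index_date"]]
    follow_ups = determine_follow_up(
        collect_claim_dates(tables), patients, eligible, win.study_end,
        gap_days=config.eligibility.followup_gap_days)
    sct = detect_sct(tables["stays"], tables["cost_items"], follow_ups,
                     config.code_lists)
    charlson = charlson_score(tables["diagnoses"], eligible)

    cohort = eligible.merge(patients[["patient_id", "birth_year", "sex"]],
                            on="patient_id", how="left")
    cohort["age_at_index"] = (pd.DatetimeIndex(cohort["index_date"]).year
                              - cohort["birth_year"]).astype(int)

    waterfall_exclusions = [
        ("diagnosis_not_confirmed",
         len(no_diag) + int((~confirmation["confirmed"]).sum())),
        ("no_diagnosis_in_window",
         int((confirmation["confirmed"]
              & confirmation["candidate_index_date"].isna()).sum())),
    ]
    rule_counts = failed.groupby("first_failed_rule")["patient_id"].nunique()
    for rule in RULE_ORDER:
        waterfall_exclusions.append((rule, int(rule_counts.get(rule, 0))))
    waterfall = attrition_waterfall(("identified", len(patients)),
                                    waterfall_exclusions)

    logger.info("cohort: %d identified -> %d eligible", len(patients), len(cohort))
    return {"cohort": cohort, "verdicts": verdicts, "exclusion_log": exclusion_log,
            "follow_ups": follow_ups, "sct": sct, "charlson": charlson,
            "waterfall": waterfall}


def lots_stage(tables: dict[str, pd.DataFrame], cohort: pd.DataFrame,
               follow_ups: pd.DataFrame, config: PipelineConfig,
               catalogue: DrugCatalogue | None = None) -> dict:
    catalogue = catalogue or DrugCatalogue.default()
    disp = tables["dispensings"]
    fu = follow_ups.set_index("patient_id")
    idx = disp["patient_id"].map(fu["index_date"])
    end = disp["patient_id"].map(fu["end_date"])
    observed = disp.loc[idx.notna() & (disp["dispense_date"] >= idx)
                        & (disp["dispense_date"] <= end)]

    episodes = build_episodes(
        observed, catalogue,
        include_partially_observable=config.lot.include_partially_observable,
        grace_overrides=config.lot.grace_overrides)
    lots = derive_lots(episodes, config.lot, follow_ups)
    lots = label_lots(lots, config.regimen_precedence)
    counts = lot_counts(lots, cohort["patient_id"])
    km = km_curves_frame(lots)
    logger.info("lots: %d lines over %d patients (%d undetermined)",
                len(lots), len(counts), int((counts["n_lots"] == 0).sum()))
    return {"lots": lots, "lot_counts": counts, "km_curves": km}


def costs_stage(tables: dict[str, pd.DataFrame], follow_ups: pd.DataFrame,
                sct: pd.DataFrame, lots: pd.DataFrame, config: PipelineConfig,
                catalogue: DrugCatalogue | None = None) -> dict:
    catalogue = catalogue or DrugCatalogue.default()
    ledger = clip_to_follow_up(build_ledger(tables, config.cost), follow_ups)
    ledger = tag_mm_treatment_admin(ledger, catalogue, config.code_lists,
                                    config.cost)
    ledger = tag_mm_related(ledger, config.code_lists, config.cost)

    outputs = {
        "table_allcause": build_allcause_table(ledger, follow_ups).reset_index(),
        "rate_report": rate_report(ledger, follow_ups).reset_index(),
        "table_mm_admin_by_lot": build_mm_admin_by_lot(
            ledger, follow_ups, sct, lots, config.cost),
    }
    for stratum, (led, fus) in split_by_sct(ledger, follow_ups, sct).items():
        outputs[f"table_allcause_{stratum}"] = build_allcause_table(
            led, fus).reset_index()
    events, summary = aoe_hospitalisations(
        tables["stays"], follow_ups, config.code_lists, sct=sct, lots=lots,
        cost_params=config.cost)
    outputs["aoe_events"] = events
    outputs["aoe_summary"] = summary
    logger.info("costs: %d ledger rows, %.0f EUR total", len(ledger),
                ledger["cost_eur_2019"].sum())
    return {"ledger": ledger, "outputs": outputs}


def report_stage(cohort, follow_ups, lot_count_table, charlson, sct, lots) -> dict:
    table1 = render_table1(cohort, follow_ups, lot_count_table, charlson, sct)
    regimen = render_regimen_figure(lots, sct)
    return {"table1": table1, "regimen_frequency": regimen}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path,
                 in_dir: str | Path | None = None,
                 sim_config: SimConfig | None = None,
                 seed: int | None = None,
                 write: bool = True) -> PipelineResult:
    """Execute every stage; returns all frames and writes CSV outputs.

    Inputs come either from ``in_dir`` (five claims CSVs) or from the
    synthetic generator (``sim_config``, or ``config.simulate`` settings).
    ``seed`` overrides the generator seed.
    """
    out_dir = Path(out_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
    catalogue = DrugCatalogue.default()

    ground_truth = None
    input_digests = {}
    if in_dir is not None:
        tables = load_claims(in_dir)
        input_digests = {s.name: _digest(Path(in_dir) / s.name)
                         for s in CLAIMS_TABLES.values()}
    else:
        if sim_config is None:
            section = config.simulate
            payload = section.model_dump() if section is not None else {}
            sim_config = SimConfig.model_validate(payload or {"n_patients": 200})
        if seed is not None:
            sim_config = sim_config.model_copy(update={"seed": seed})
        logger.info("simulate: n=%d seed=%d", sim_config.n_patients, sim_config.seed)
        tables, ground_truth = generate_population(sim_config, catalogue)
        tables, ground_truth = inject_protocol_violations(
            tables, ground_truth, sim_config.violations, seed=sim_config.seed,
            inclusion_start=sim_config.inclusion_start)
        if write:
            write_population(tables, ground_truth, out_dir / "claims")

    stage1 = cohort_stage(tables, config, catalogue)
    stage2 = lots_stage(tables, stage1["cohort"], stage1["follow_ups"], config,
                        catalogue)
    stage3 = costs_stage(tables, stage1["follow_ups"], stage1["sct"],
                         stage2["lots"], config, catalogue)
    stage4 = report_stage(stage1["cohort"], stage1["follow_ups"],
                          stage2["lot_counts"], stage1["charlson"],
                          stage1["sct"], stage2["lots"])

    outputs: dict[str, pd.DataFrame] = {
        "cohort": stage1["cohort"], "exclusion_log": stage1["exclusion_log"],
        "followup": stage1["follow_ups"], "sct": stage1["sct"],
        "charlson": stage1["charlson"], "attrition": stage1["waterfall"],
        "lots": stage2["lots"], "lot_counts": stage2["lot_counts"],
        "km_curves": stage2["km_curves"],
        "table1": stage4["table1"],
        "regimen_frequency": stage4["regimen_frequency"],
    }
    outputs.update(stage3["outputs"])

    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            config.model_dump_json().encode()).hexdigest(),
        "seed": (sim_config.seed if sim_config is not None else None),
        "input_digests": input_digests,
        "row_counts": {
            "patients": len(tables["patients"]),
            "diagnoses": len(tables["diagnoses"]),
            "dispensings": len(tables["dispensings"]),
            "stays": len(tables["stays"]),
            "cost_items": len(tables["cost_items"]),
            "cohort": len(stage1["cohort"]),
            "lots": len(stage2["lots"]),
            "ledger": len(stage3["ledger"]),
        },
        "timestamp": dt.datetime.now(dt.timezone.utc).isoformat(timespec="seconds"),
    }

    if write:
        for name, frame in outputs.items():
            write_table(frame, out_dir / f"{name}.csv")
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        tables=tables, ground_truth=ground_truth, cohort=stage1["cohort"],
        verdicts=stage1["verdicts"], exclusion_log=stage1["exclusion_log"],
        follow_ups=stage1["follow_ups"], sct=stage1["sct"],
        charlson=stage1["charlson"], lots=stage2["lots"],
        lot_count_table=stage2["lot_counts"], outputs=outputs,
        manifest=manifest)
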