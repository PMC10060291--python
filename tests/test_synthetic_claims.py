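import hashlib
import json

import pandas as pd
import pydantic
import pytest

from mmlot.schemas import CLAIMS_TABLES, GROUND_TRUTH
from mmlot.synthetic_claims import (
    NoiseConfig,
    SimConfig,
    ViolationRates,
    generate_population,
    inject_protocol_violations,
    sim_config_json_schema,
    write_population,
)

from _oracle import oracle_lots


def _digests(out_dir):
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out_dir.glob("*.csv"))}


def test_zero_patients_gives_headers_only(tmp_path):
    tables, truth = generate_population(SimConfig(n_patients=0, seed=5))
    for name, df in tables.items():
        assert len(df) == 0
        assert list(df.columns) == CLAIMS_TABLES[name].column_names
    assert len(truth) == 0
    paths = write_population(tables, truth, tmp_path)
    for p in paths:
        assert p.read_text().count("\n") == 1  # header line only


def test_determinism_identical_sha256(tmp_path):
    cfg = SimConfig(n_patients=50, seed=1)
    t1, g1 = generate_population(cfg)
    t2, g2 = generate_population(cfg)
    write_population(t1, g1, tmp_path / "a")
    write_population(t2, g2, tmp_path / "b")
    assert _digests(tmp_path / "a") == _digests(tmp_path / "b")


def test_different_seed_changes_output(tmp_path):
    t1, _ = generate_population(SimConfig(n_patients=20, seed=1))
    t2, _ = generate_population(SimConfig(n_patients=20, seed=2))
    assert not t1["dispensings"].equals(t2["dispensings"])


def test_single_lot_mass_gives_one_lot_each():
    cfg = SimConfig(n_patients=60, seed=3, n_lot_distribution={"1": 1.0})
    _, truth = generate_population(cfg)
    treated = truth.loc[truth["true_eligible"]]
    assert len(treated) > 0
    assert (treated["true_n_lots"] == 1).all()


def test_invalid_config_names_field():
    with pytest.raises(pydantic.ValidationError) as err:
        SimConfig(n_patients=10, sct_probability=1.5)
    assert "sct_probability" in str(err.value)
    with pytest.raises(pydantic.ValidationError) as err:
        SimConfig(n_patients=10, n_lot_distribution={"1": 0.5, "2": 0.4})
    assert "n_lot_distribution" in str(err.value)


def test_schema_validity_of_generated_tables():
    tables, truth = generate_population(SimConfig(n_patients=40, seed=9))
    for name, schema in CLAIMS_TABLES.items():
        schema.validate(tables[name])  # must not raise
    GROUND_TRUTH.validate(truth)


def test_dispensings_lie_inside_true_lot_windows():
    cfg = SimConfig(n_patients=40, seed=13)
    tables, truth = generate_population(cfg)
    lots_by_pid = {r.patient_id: json.loads(r.true_lot_json)
                   for r in truth.itertuples(index=False)}
    disp = tables["dispensings"]
    # ignore exempt steroids, which are dispensed alongside any line
    exempt_atc = {"H02AB02", "H02AB07"}
    disp = disp.loc[~disp["atc_code"].isin(exempt_atc)]
    for rec in disp.itertuples(index=False):
        lots = lots_by_pid[rec.patient_id]
        ok = any(pd.Timestamp(l["start"]) <= rec.dispense_date
                 <= pd.Timestamp(l["end"]) for l in lots)
        assert ok, f"{rec.patient_id} dispensing {rec.dispense_date} outside truth"


def test_label_soundness_against_brute_force_oracle():
    """noise=0: true LOT count == brute-force segmentation of the stream."""
    tables, truth = generate_population(SimConfig(n_patients=50, seed=21))
    disp = tables["dispensings"]
    grace_by_atc = {"L04AX04": 42, "L04AX06": 42, "L01XG03": 42, "L01AA03": 42,
                    "L01AA01": 42, "L01XG01": 49, "L01XG02": 49, "L01FC01": 49,
                    "L01AA09": 49, "L01DB01": 49}
    base = pd.Timestamp("2008-01-01")
    for rec in truth.itertuples(index=False):
        mine = disp.loc[(disp["patient_id"] == rec.patient_id)
                        & disp["atc_code"].isin(grace_by_atc)]
        events = [((d - base).days, a) for d, a in
                  zip(mine["dispense_date"], mine["atc_code"])]
        fu = (rec.true_followup_end - base).days
        lots = oracle_lots(events, grace_by_atc, fu_end=fu)
        assert len(lots) == rec.true_n_lots, rec.patient_id


def test_violation_rate_zero_is_identity():
    tables, truth = generate_population(SimConfig(n_patients=20, seed=4))
    out_tables, out_truth = inject_protocol_violations(tables, truth,
                                                       ViolationRates(), seed=4)
    assert out_tables is tables
    assert out_truth is truth


def test_violation_untreated_rate_one_marks_everyone():
    tables, truth = generate_population(SimConfig(n_patients=25, seed=6))
    out_tables, out_truth = inject_protocol_violations(
        tables, truth, ViolationRates(untreated=1.0), seed=6)
    assert len(out_tables["dispensings"]) == 0
    assert (~out_truth["true_eligible"]).all()
    assert (out_truth["true_fail_reason"] == "no_mm_treatment").all()


def test_mixed_violation_rates_bookkeeping_exact():
    """With noise=0, per-reason injected counts equal truth-label counts."""
    tables, truth = generate_population(SimConfig(n_patients=150, seed=8))
    rates = ViolationRates(untreated=0.10, late_start=0.10, prior_malignancy=0.05)
    out_tables, out_truth = inject_protocol_violations(tables, truth, rates, seed=8)
    reasons = out_truth.loc[~out_truth["true_eligible"], "true_fail_reason"]
    counts = reasons.value_counts()
    # every ineligible patient carries exactly one of the injected reasons
    assert set(counts.index) <= {"no_mm_treatment", "treatment_after_30d",
                                 "other_malignancy"}
    assert counts.sum() == (~out_truth["true_eligible"]).sum()
    assert counts.sum() > 0


def test_sim_config_schema_is_publishable():
    schema = sim_config_json_schema()
    assert schema["type"] == "object"
    assert "n_patients" in schema["properties"]
    json.dumps(schema)  # serialisable
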