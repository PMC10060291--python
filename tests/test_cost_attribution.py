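import pandas as pd
import pytest

from mmlot.cost_engine import (
    build_ledger,
    tag_mm_related,
    tag_mm_treatment_admin,
)
from mmlot.synthetic_claims import SimConfig, generate_population

from conftest import cost_items_frame, day, dispensings_from_days, stays_frame


def _tagged(tables):
    ledger = tag_mm_treatment_admin(build_ledger(tables))
    return tag_mm_related(ledger)


def _row(ledger, category):
    sub = ledger.loc[ledger["category"] == category]
    assert len(sub) == 1
    return sub.iloc[0]


def test_chemo_stay_with_mm_related_dx_fully_flagged():
    tables = {"stays": stays_frame([
        {"patient_id": "P1", "admit_date": day(10), "stay_type": "chemo_session",
         "primary_dx": "Z51.1", "related_dx": "C90.0", "cost_eur": 420.0}])}
    ledger = _tagged(tables)
    row = _row(ledger, "chemo_session")
    assert row["mm_treatment_admin"]
    assert row["cost_eur_2019"] == 420.0  # entire stay cost carries the flag


def test_chemo_stay_without_mm_dx_not_flagged():
    tables = {"stays": stays_frame([
        {"patient_id": "P1", "admit_date": day(10), "stay_type": "chemo_session",
         "primary_dx": "Z51.1", "cost_eur": 420.0}])}
    row = _row(_tagged(tables), "chemo_session")
    assert not row["mm_treatment_admin"]
    assert not row["mm_related"]


def test_mm_drug_dispensing_flagged_any_setting():
    tables = {"dispensings": dispensings_from_days([
        ("bortezomib", 0), ("lenalidomide", 0), ("dexamethasone", 0)])}
    ledger = _tagged(tables)
    assert ledger["mm_treatment_admin"].all()  # dexamethasone is MM-indicated


def test_transport_next_day_after_dispensing_flagged():
    tables = {
        "dispensings": dispensings_from_days([("lenalidomide", 10)]),
        "cost_items": cost_items_frame([
            {"patient_id": "P1", "date": day(11), "category": "transport",
             "cost_eur": 60.0},
            {"patient_id": "P1", "date": day(13), "category": "transport",
             "cost_eur": 60.0}])}
    ledger = _tagged(tables)
    transport = ledger.loc[ledger["category"] == "transport"].sort_values("date")
    assert list(transport["mm_treatment_admin"]) == [True, False]


def test_sick_leave_seven_day_window():
    stays = stays_frame([
        {"patient_id": "P1", "admit_date": day(0), "discharge_date": day(0),
         "stay_type": "chemo_session", "primary_dx": "Z51.1",
         "related_dx": "C90.0", "cost_eur": 400.0}])
    tables = {"stays": stays, "cost_items": cost_items_frame([
        {"patient_id": "P1", "date": day(7), "category": "sick_leave_invalidity",
         "cost_eur": 500.0, "days": 10},
        {"patient_id": "P2", "date": day(8), "category": "sick_leave_invalidity",
         "cost_eur": 500.0, "days": 10}])}
    # P2 has no MM event: out of window by construction
    ledger = _tagged(tables)
    sick = ledger.loc[ledger["category"] == "sick_leave_invalidity"]
    flags = dict(zip(sick["patient_id"], sick["mm_treatment_admin"]))
    assert flags == {"P1": True, "P2": False}


def test_sick_leave_eight_days_after_not_flagged():
    tables = {
        "dispensings": dispensings_from_days([("lenalidomide", 0)]),
        "cost_items": cost_items_frame([
            {"patient_id": "P1", "date": day(8),
             "category": "sick_leave_invalidity", "cost_eur": 500.0,
             "days": 10}])}
    row = _row(_tagged(tables), "sick_leave_invalidity")
    assert not row["mm_treatment_admin"]


def test_stay_with_associated_mm_dx_related_only():
    tables = {"stays": stays_frame([
        {"patient_id": "P1", "admit_date": day(0), "stay_type": "mco_complete",
         "primary_dx": "J18.9", "associated_dx": "C90.1", "cost_eur": 900.0}])}
    row = _row(_tagged(tables), "hospitalisation_excl_chemo")
    assert not row["mm_treatment_admin"]
    assert row["mm_related"]


def test_rehab_directly_following_mm_stay_flagged():
    tables = {"stays": stays_frame([
        {"patient_id": "P1", "admit_date": day(0), "discharge_date": day(10),
         "stay_type": "mco_complete", "primary_dx": "C90.0", "cost_eur": 5000.0},
        {"patient_id": "P1", "admit_date": day(10), "discharge_date": day(30),
         "stay_type": "rehab", "primary_dx": "Z50.1", "cost_eur": 2500.0},
        {"patient_id": "P1", "admit_date": day(200), "discharge_date": day(220),
         "stay_type": "rehab", "primary_dx": "Z50.1", "cost_eur": 2500.0}])}
    ledger = _tagged(tables)
    rehab = ledger.loc[ledger["category"] == "rehab"].sort_values("date")
    assert list(rehab["mm_related"]) == [True, False]
    assert not rehab["mm_treatment_admin"].any()


def test_home_hospitalisation_with_mm_dx_flagged():
    tables = {"stays": stays_frame([
        {"patient_id": "P1", "admit_date": day(0), "stay_type": "home",
         "related_dx": "C90.0", "cost_eur": 1500.0}])}
    assert _row(_tagged(tables), "home_hospitalisation")["mm_related"]


def test_outpatient_lab_test_never_mm_related():
    tables = {
        "dispensings": dispensings_from_days([("lenalidomide", 0)]),
        "cost_items": cost_items_frame([
            {"patient_id": "P1", "date": day(0), "category": "lab_test",
             "cost_eur": 45.0}])}
    row = _row(_tagged(tables), "lab_test")
    assert not row["mm_related"]


def test_flag_monotonicity_on_simulated_ledger():
    tables, _ = generate_population(SimConfig(n_patients=40, seed=17))
    ledger = _tagged(tables)
    assert (ledger["mm_related"] | ~ledger["mm_treatment_admin"]).all()
    assert ledger.loc[ledger["mm_treatment_admin"], "mm_related"].all()


def test_related_requires_admin_flags_first():
    tables = {"dispensings": dispensings_from_days([("lenalidomide", 0)])}
    with pytest.raises(ValueError):
        tag_mm_related(build_ledger(tables))
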