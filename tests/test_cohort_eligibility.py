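import pandas as pd
import pytest

from mmlot.cohort_builder import apply_eligibility
from mmlot.config import EligibilityParams

from conftest import diagnoses_frame, dispensings_from_days, patients_frame

HISTORY_START = "2008-01-01"
INDEX = pd.Timestamp("2014-06-01")


def _verdict(patients, diagnoses, dispensings, index=INDEX, params=None):
    index_dates = pd.DataFrame({"patient_id": ["P1"], "index_date": [index]})
    out = apply_eligibility(patients, diagnoses, dispensings, index_dates,
                            params=params, history_start=HISTORY_START)
    return out.iloc[0]


def _base_patient(birth_year=1950):
    return patients_frame([{"patient_id": "P1", "birth_year": birth_year}])


def _mm_dx(date="2014-06-01"):
    return diagnoses_frame([("P1", "C90.0", date, "hospital_primary")])


def _disp(offset_days):
    events = [("P1", "lenalidomide", offset_days)]
    df = dispensings_from_days(events)
    df["dispense_date"] = INDEX + pd.Timedelta(days=offset_days)
    return df


def test_eligible_baseline():
    v = _verdict(_base_patient(), _mm_dx(), _disp(5))
    assert v["eligible"]
    assert v["first_failed_rule"] is None


def test_age_exactly_18_ineligible_by_default():
    # "older than 18" read strictly: completed age 18 at index fails
    v = _verdict(_base_patient(birth_year=1996), _mm_dx(), _disp(5))
    assert not v["eligible"]
    assert v["first_failed_rule"] == "age_over_18"


def test_age_rule_configurable_to_ge18():
    params = EligibilityParams(age_rule="ge18")
    v = _verdict(_base_patient(birth_year=1996), _mm_dx(), _disp(5), params=params)
    assert v["eligible"]


def test_dispensing_on_day_30_is_eligible():
    v = _verdict(_base_patient(), _mm_dx(), _disp(30))
    assert v["eligible"]


def test_dispensing_on_day_31_fails_late():
    v = _verdict(_base_patient(), _mm_dx(), _disp(31))
    assert v["first_failed_rule"] == "treatment_after_30d"


def test_no_dispensing_fails_untreated():
    empty = dispensings_from_days([("P1", "lenalidomide", 0)]).iloc[0:0]
    v = _verdict(_base_patient(), _mm_dx(), empty)
    assert v["first_failed_rule"] == "no_mm_treatment"


def test_c44_history_not_an_exclusion():
    diag = diagnoses_frame([
        ("P1", "C90.0", "2014-06-01", "hospital_primary"),
        ("P1", "C44.9", "2012-06-01", "hospital_primary")])  # 2 years pre-index
    v = _verdict(_base_patient(), diag, _disp(5))
    assert v["eligible"]


def test_other_malignancy_within_5_years_excludes():
    diag = diagnoses_frame([
        ("P1", "C90.0", "2014-06-01", "hospital_primary"),
        ("P1", "C50.9", "2011-01-01", "hospital_primary")])
    v = _verdict(_base_patient(), diag, _disp(5))
    assert v["first_failed_rule"] == "other_malignancy"


def test_other_malignancy_older_than_5_years_ignored():
    diag = diagnoses_frame([
        ("P1", "C90.0", "2014-06-01", "hospital_primary"),
        ("P1", "C50.9", "2009-01-01", "hospital_primary")])
    v = _verdict(_base_patient(), diag, _disp(5))
    assert v["eligible"]


def test_prior_mm_within_year_excludes():
    # pre-window record 2012-06-01 with index 2013-02-01: inside the 365-day
    # lookback, so the prior-MM exclusion applies after index setting
    index = pd.Timestamp("2013-02-01")
    diag = diagnoses_frame([
        ("P1", "C90.0", "2012-06-01", "hospital_primary"),
        ("P1", "C90.0", "2013-02-01", "hospital_primary")])
    disp = _disp(5)
    disp["dispense_date"] = index + pd.Timedelta(days=5)
    v = _verdict(_base_patient(), diag, disp, index=index)
    assert v["first_failed_rule"] == "prior_mm"


def test_missing_demographics():
    patients = patients_frame([{"patient_id": "P9", "birth_year": 1950}])
    v = _verdict(patients, _mm_dx(), _disp(5))
    assert v["first_failed_rule"] == "missing_data"


def test_general_scheme_required():
    patients = patients_frame([{"patient_id": "P1", "birth_year": 1950,
                                "general_scheme": False}])
    v = _verdict(patients, _mm_dx(), _disp(5))
    assert v["first_failed_rule"] == "general_scheme"


def test_insufficient_history():
    index = pd.Timestamp("2008-06-01")
    diag = diagnoses_frame([("P1", "C90.0", "2008-06-01", "hospital_primary")])
    disp = _disp(5)
    disp["dispense_date"] = index + pd.Timedelta(days=5)
    v = _verdict(_base_patient(), diag, disp, index=index)
    assert v["first_failed_rule"] == "insufficient_history"


def test_rule_order_fixed():
    # an under-age patient with a malignancy history fails on age first
    diag = diagnoses_frame([
        ("P1", "C90.0", "2014-06-01", "hospital_primary"),
        ("P1", "C50.9", "2012-06-01", "hospital_primary")])
    v = _verdict(_base_patient(birth_year=1997), diag, _disp(40))
    assert v["first_failed_rule"] == "age_over_18"


def test_order_insensitivity_of_verdicts():
    diag = diagnoses_frame([
        ("P1", "C90.0", "2014-06-01", "hospital_primary"),
        ("P1", "C50.9", "2011-01-01", "hospital_primary")])
    disp = _disp(5)
    v1 = _verdict(_base_patient(), diag, disp)
    v2 = _verdict(_base_patient(), diag.iloc[::-1].reset_index(drop=True),
                  disp.iloc[::-1].reset_index(drop=True))
    assert v1["first_failed_rule"] == v2["first_failed_rule"]
    assert v1["eligible"] == v2["eligible"]
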