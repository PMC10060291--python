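import numpy as np
import pandas as pd
import pytest

from mmlot.reporting import (
    attrition_waterfall,
    distribution_rows,
    mean_per_person_keur,
    pct,
    render_regimen_figure,
    render_table1,
    round_half_up,
    share_pct,
    summary_rows,
)
from mmlot.lot_engine import label_lots

from conftest import day, follow_up_frame


def test_pct_rounding():
    assert pct(2554, 6413) == 39.8
    assert pct(1, 3) == 33.3
    assert np.isnan(pct(1, 0))


def test_round_half_up_not_bankers():
    assert round_half_up(0.5) == 1.0
    assert round_half_up(1.5) == 2.0
    assert round_half_up(2.675, 2) == 2.68
    assert round_half_up(-0.5) == -1.0


def test_mean_per_person():
    assert mean_per_person_keur(816.00, 6413) == 127.24


def test_share():
    assert share_pct(35.19, 72.37) == 48.6


def test_distribution_rows_partition_to_100():
    rows = distribution_rows({"a": 33, "b": 33, "c": 34}, 100)
    assert sum(r["pct"] for r in rows) == pytest.approx(100.0, abs=0.3)
    assert sum(r["n"] for r in rows) == 100


def test_summary_rows_hand_checked_ages():
    ages = pd.Series([52, 55, 58, 60, 61, 63, 66, 70, 74, 81])
    rows = {r["row"]: r["value"] for r in summary_rows(ages)}
    assert rows["mean"] == pytest.approx(64.0)
    assert rows["median"] == pytest.approx(62.0)
    assert rows["min"] == 52 and rows["max"] == 81
    assert rows["iqr"] == pytest.approx(
        np.percentile(ages, 75) - np.percentile(ages, 25), abs=0.05)


def test_attrition_waterfall_counts_non_increasing():
    wf = attrition_waterfall(("identified", 1000),
                             [("rule_a", 100), ("rule_b", 50), ("rule_c", 0)])
    assert list(wf["remaining"]) == [1000, 900, 850, 850]
    assert (wf["remaining"].diff().dropna() <= 0).all()
    assert wf.loc[1, "pct_of_initial"] == 10.0


def test_attrition_rejects_overdraw():
    with pytest.raises(ValueError):
        attrition_waterfall(("identified", 10), [("rule_a", 11)])


def _lots_frame(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "lot_number", "regimen"])
    df["start"] = day(0)
    df["end"] = day(100)
    df["end_reason"] = "discontinuation"
    df["duration_days"] = 100
    return label_lots(df)


def test_regimen_figure_single_regimen_is_100pct():
    lots = _lots_frame([("P1", 1, "bortezomib"), ("P2", 1, "bortezomib")])
    out = render_regimen_figure(lots)
    row = out.loc[(out["line"] == "1")
                  & (out["regimen_label"] == "bortezomib-based")].iloc[0]
    assert row["n"] == 2
    assert row["pct"] == 100.0


def test_regimen_figure_distinct_count():
    lots = _lots_frame([("P1", 1, "bortezomib+lenalidomide"),
                        ("P2", 1, "bortezomib+thalidomide"),
                        ("P3", 1, "bortezomib+lenalidomide")])
    out = render_regimen_figure(lots)
    distinct = out.loc[(out["line"] == "1")
                       & (out["regimen_label"] == "distinct_regimens")].iloc[0]
    assert distinct["n"] == 2


def test_regimen_frequencies_match_menu_within_3se():
    """Labels drawn from a known menu recover the probabilities at n=2000."""
    rng = np.random.default_rng(42)
    menu = [("bortezomib", 0.7), ("lenalidomide", 0.2), ("pomalidomide", 0.1)]
    drugs = rng.choice([m[0] for m in menu], size=2000,
                       p=[m[1] for m in menu])
    lots = _lots_frame([(f"P{i}", 1, d) for i, d in enumerate(drugs)])
    out = render_regimen_figure(lots).set_index("regimen_label")
    n = 2000
    for drug, p in menu:
        observed = out.loc[f"{drug}-based", "n"] / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) <= 3 * se


def test_render_table1_percentages_and_sections():
    cohort = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(4)],
        "index_date": [day(0)] * 4,
        "birth_year": [1950, 1960, 1940, 1985],
        "sex": ["M", "F", "M", "F"],
        "age_at_index": [64, 54, 74, 29]})
    fu = follow_up_frame([("P0", 0, 365, "death"),
                          ("P1", 0, 730, "end_of_observation"),
                          ("P2", 0, 100, "death"),
                          ("P3", 0, 400, "end_of_observation")])
    counts = pd.DataFrame({"patient_id": cohort["patient_id"],
                           "n_lots": [1, 2, 0, 5]})
    charlson = pd.DataFrame({"patient_id": cohort["patient_id"],
                             "score": [2, 3, 2, 6],
                             "conditions": ["", "", "", ""]})
    sct = pd.DataFrame({"patient_id": cohort["patient_id"],
                        "sct": [True, False, False, True],
                        "sct_date": [day(90), pd.NaT, pd.NaT, day(120)],
                        "graft_type": ["autologous", None, None, "autologous"]})
    out = render_table1(cohort, fu, counts, charlson, sct)
    total = out.loc[out["stratum"] == "total"]
    bands = total.loc[total["section"] == "age_band"]
    assert bands["pct"].sum() == pytest.approx(100.0, abs=0.3)
    lot_rows = total.loc[total["section"] == "n_lots"].set_index("row")
    assert lot_rows.loc["undetermined", "n"] == 1
    assert lot_rows.loc["5+", "n"] == 1
    death = total.loc[(total["section"] == "end_reason")
                      & (total["row"] == "death")].iloc[0]
    assert death["n"] == 2 and death["pct"] == 50.0
    n_sct = out.loc[(out["stratum"] == "sct")
                    & (out["section"] == "population")].iloc[0]
    assert n_sct["n"] == 2
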