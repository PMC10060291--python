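import pandas as pd
import pytest

from mmlot.config import LotParams
from mmlot.lot_engine import build_episodes, derive_lots

from conftest import DRUG_A, DRUG_B, DRUG_C, EXEMPT, day, dispensings_from_days


def _lots(events, params=None, follow_ups=None):
    eps = build_episodes(dispensings_from_days(events))
    return derive_lots(eps, params or LotParams(), follow_ups)


def steady(drug, start, stop, step=28):
    return [(drug, d) for d in range(start, stop + 1, step)]


def test_new_drug_starts_second_line_with_carryover():
    # A steady through day 112, B added day 150 while A still in exposure
    lots = _lots(steady(DRUG_A, 0, 120) + [(DRUG_B, 150)])
    assert len(lots) == 2
    first, second = lots.iloc[0], lots.iloc[1]
    assert first["regimen"] == DRUG_A
    assert first["end_reason"] == "new_drug"
    assert first["end"] == day(149)  # day before the new drug starts
    assert second["regimen"] == f"{DRUG_A}+{DRUG_B}"  # carryover combination
    assert second["start"] == day(150)


def test_discontinuation_gap_after_grace():
    # A on days 0-56 (grace 42 -> exposure end 98); next A on day 200:
    # gap 102 >= 90 ends line 1 at day 98
    lots = _lots(steady(DRUG_A, 0, 56) + [(DRUG_A, 200)])
    assert len(lots) == 2
    assert lots.iloc[0]["end"] == day(98)
    assert lots.iloc[0]["end_reason"] == "discontinuation"
    assert lots.iloc[1]["start"] == day(200)
    assert lots.iloc[1]["regimen"] == DRUG_A


def test_regimen_window_combines_drugs():
    lots = _lots([(DRUG_A, 0), (DRUG_B, 20)])
    assert len(lots) == 1
    assert lots.iloc[0]["regimen"] == f"{DRUG_A}+{DRUG_B}"


def test_window_boundary_day_28_included():
    lots = _lots([(DRUG_A, 0), (DRUG_B, 28)])
    assert len(lots) == 1
    # one day past the window: a new drug splits (extension disabled to
    # isolate the boundary)
    params = LotParams(combination_extension=False)
    lots = _lots([(DRUG_A, 0), (DRUG_A, 28), (DRUG_B, 29)], params)
    assert len(lots) == 2


def test_corticosteroid_never_advances_line():
    lots = _lots(steady(DRUG_A, 0, 168) + [(EXEMPT, 150)])
    assert len(lots) == 1
    assert lots.iloc[0]["regimen"] == DRUG_A


def test_combination_extension_when_regimen_continues():
    # A runs to day 224 (exposure 266); B at day 60 overlaps >= 40 days
    lots = _lots(steady(DRUG_A, 0, 224) + [(DRUG_B, 60)])
    assert len(lots) == 1
    assert lots.iloc[0]["regimen"] == f"{DRUG_A}+{DRUG_B}"


def test_combination_extension_disabled_splits():
    params = LotParams(combination_extension=False)
    lots = _lots(steady(DRUG_A, 0, 224) + [(DRUG_B, 60)], params)
    assert len(lots) == 2
    assert lots.iloc[1]["regimen"] == f"{DRUG_A}+{DRUG_B}"


def test_censoring_at_follow_up_end():
    fu = pd.DataFrame({"patient_id": ["P1"], "index_date": [day(0)],
                       "end_date": [day(70)]})
    lots = _lots(steady(DRUG_A, 0, 56), follow_ups=fu)
    assert len(lots) == 1
    assert lots.iloc[0]["end_reason"] == "censored"
    assert lots.iloc[0]["end"] == day(70)


def test_unconfirmed_gap_at_stream_end_is_censored():
    # exposure ends day 98, follow-up ends day 150: gap of 52 < 90 observed
    fu = pd.DataFrame({"patient_id": ["P1"], "index_date": [day(0)],
                       "end_date": [day(150)]})
    lots = _lots(steady(DRUG_A, 0, 56), follow_ups=fu)
    assert lots.iloc[0]["end_reason"] == "censored"
    assert lots.iloc[0]["end"] == day(98)


def test_fully_observed_gap_at_stream_end_discontinues():
    fu = pd.DataFrame({"patient_id": ["P1"], "index_date": [day(0)],
                       "end_date": [day(400)]})
    lots = _lots(steady(DRUG_A, 0, 56), follow_ups=fu)
    assert lots.iloc[0]["end_reason"] == "discontinuation"
    assert lots.iloc[0]["end"] == day(98)


def test_exempt_only_stream_gives_zero_lots():
    lots = _lots([(EXEMPT, 0), (EXEMPT, 28)])
    assert len(lots) == 0


def test_numbering_gapless_from_one():
    events = (steady(DRUG_A, 0, 56) + steady(DRUG_B, 250, 306)
              + steady(DRUG_C, 500, 556))
    lots = _lots(events)
    assert list(lots["lot_number"]) == [1, 2, 3]
    assert (lots["start"].diff().dropna() > pd.Timedelta(0)).all()


def test_lots_non_overlapping_ordered():
    events = steady(DRUG_A, 0, 120) + [(DRUG_B, 150)] + steady(DRUG_B, 150, 250)
    lots = _lots(events)
    for i in range(len(lots) - 1):
        assert lots.iloc[i]["end"] < lots.iloc[i + 1]["start"]


def test_monotone_splitting():
    """Inserting a claim-free interval >= gap+grace adds exactly one line."""
    base = steady(DRUG_A, 0, 112)
    lots0 = _lots(base)
    shift = 42 + 90 + 10  # grace + gap + margin
    split_at = 56
    shifted = [(d, t) if t <= split_at else (d, t + shift) for d, t in base]
    lots1 = _lots(shifted)
    assert len(lots1) == len(lots0) + 1
    # removing the interval restores the original segmentation
    restored = [(d, t) if t <= split_at else (d, t - shift) for d, t in shifted]
    pd.testing.assert_frame_equal(_lots(restored), lots0)


def test_ties_same_day_new_drugs_join_same_line():
    lots = _lots(steady(DRUG_A, 0, 56) + [(DRUG_B, 250), (DRUG_C, 250)])
    assert len(lots) == 2
    assert lots.iloc[1]["regimen"] == "+".join(sorted([DRUG_B, DRUG_C]))


def test_duration_matches_dates():
    lots = _lots(steady(DRUG_A, 0, 56))
    assert lots.iloc[0]["duration_days"] == 98
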