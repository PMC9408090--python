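"""Threshold classifiers, risk counts and multiple-risk tiers."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from fifocost import risk_scoring as rs
from fifocost.reference import CONDITIONS


@pytest.mark.parametrize("score,expected", [(22, True), (21, False), (10, False), (50, True)])
def test_psychological_distress_threshold(score, expected):
    assert rs.classify_psychological_distress(score) is expected


@pytest.mark.parametrize("score,expected", [(49.9, True), (50.0, False), (100, False), (0, True)])
def test_physical_health_threshold(score, expected):
    assert rs.classify_physical_health(score) is expected


@pytest.mark.parametrize("hours,quality,expected", [
    (6.5, "very good", True),   # short duration alone flags
    (8.0, "fairly bad", True),  # poor quality alone flags (and/or rule)
    (7.0, "good", False),
    (6.9, "very bad", True),
])
def test_sleep_disjunction(hours, quality, expected):
    assert rs.classify_sleep(hours, quality) is expected


@pytest.mark.parametrize("score,gender,expected", [
    (4, "male", True), (3, "male", False), (3, "female", True),
    (2, "female", False), (12, "male", True),
])
def test_alcohol_sex_specific_cutoffs(score, gender, expected):
    assert rs.classify_alcohol(score, gender) is expected


@pytest.mark.parametrize("status,expected", [
    ("current", True), ("previous", False), ("never", False)])
def test_smoking(status, expected):
    assert rs.classify_smoking(status) is expected


def test_ipaq_met_minutes():
    assert rs.ipaq_met_minutes([]) == 0
    assert rs.ipaq_met_minutes([("moderate", 5, 30)]) == 600.0
    assert rs.ipaq_met_minutes(
        [("walking", 7, 10), ("vigorous", 2, 20)]) == pytest.approx(551.0)


@pytest.mark.parametrize("met,expected", [(599, True), (600, False), (0, True)])
def test_physical_activity_threshold(met, expected):
    assert rs.classify_physical_activity(met) is expected


def test_bmi_and_weight_bands():
    assert rs.bmi(80, 1.79) == pytest.approx(24.968, abs=1e-3)
    assert rs.classify_weight(rs.bmi(80, 1.79)) is False
    assert rs.classify_weight(25.0) is True      # overweight band starts at 25
    assert rs.classify_weight(18.5) is False     # healthy band is [18.5, 25)
    assert rs.classify_weight(18.4) is True
    assert rs.classify_weight(31.0) is True


@pytest.mark.parametrize("fruit,veg,expected", [
    ((2, 5), None, False), ((3, 4), None, True), ((0, 0), None, True),
    ((1.9, 8), None, True),
])
def test_diet_disjunction(fruit, veg, expected):
    f, v = fruit
    assert rs.classify_diet(f, v) is expected


@pytest.mark.parametrize("func,args", [
    (rs.classify_psychological_distress, (9,)),
    (rs.classify_psychological_distress, (51,)),
    (rs.classify_physical_health, (101,)),
    (rs.classify_sleep, (-1, "good")),
    (rs.classify_sleep, (7, "terrible")),
    (rs.classify_alcohol, (13, "male")),
    (rs.classify_alcohol, (4, "nonbinary")),
    (rs.classify_smoking, ("sometimes",)),
    (rs.classify_physical_activity, (-5,)),
    (rs.classify_diet, (-1, 5)),
])
def test_validation_errors(func, args):
    with pytest.raises(ValueError):
        func(*args)


def test_bmi_rejects_nonpositive():
    with pytest.raises(ValueError):
        rs.bmi(0, 1.8)
    with pytest.raises(ValueError):
        rs.bmi(80, -1.8)


def test_ipaq_rejects_bad_inputs():
    with pytest.raises(ValueError):
        rs.ipaq_met_minutes([("moderate", 8, 30)])
    with pytest.raises(ValueError):
        rs.ipaq_met_minutes([("moderate", 5, -1)])
    with pytest.raises(ValueError):
        rs.ipaq_met_minutes([("swimming", 5, 30)])


def test_risk_count_and_tier_exhaustive():
    """Count equals the flag sum and the tier map is total over all 2^8 combos."""
    for combo in product([False, True], repeat=8):
        flags = dict(zip(CONDITIONS, combo))
        profile = rs.RiskProfile(worker_id="w", flags=flags)
        assert profile.risk_count == sum(combo)
        expected_tier = ("low" if profile.risk_count <= 2
                         else "medium" if profile.risk_count <= 4 else "high")
        assert profile.tier == expected_tier


def test_tier_boundaries():
    assert [rs.tier_for_count(c) for c in range(9)] == [
        "low", "low", "low", "medium", "medium", "high", "high", "high", "high"]
    with pytest.raises(ValueError):
        rs.tier_for_count(9)


def _complete_record(**overrides):
    base = dict(worker_id="w0", gender="male", k10_score=12, pcs_score=55.0,
                sleep_hours=8.0, sleep_quality="good", auditc_score=1,
                smoking_status="never", met_minutes=900.0, height_m=1.80,
                weight_kg=70.0, fruit_serves=2.5, veg_serves=6.0)
    base.update(overrides)
    return base


def test_build_risk_profile_tiers():
    # failing only diet and weight: low tier
    rec = _complete_record(fruit_serves=1.0, weight_kg=95.0)
    prof = rs.build_risk_profile(rec)
    assert prof.risk_count == 2 and prof.tier == "low"
    # adding poor sleep: medium
    rec = _complete_record(fruit_serves=1.0, weight_kg=95.0, sleep_hours=5.0)
    prof = rs.build_risk_profile(rec)
    assert prof.risk_count == 3 and prof.tier == "medium"
    # five conditions: high
    rec = _complete_record(fruit_serves=1.0, weight_kg=95.0, sleep_hours=5.0,
                           smoking_status="current", met_minutes=100.0)
    prof = rs.build_risk_profile(rec)
    assert prof.risk_count == 5 and prof.tier == "high"


def test_missing_field_raises_incomplete():
    rec = _complete_record()
    del rec["k10_score"]
    with pytest.raises(rs.IncompleteRecordError) as err:
        rs.build_risk_profile(rec)
    assert "k10_score" in err.value.missing_fields


def test_classify_cohort_complete_case_exclusion():
    rows = [_complete_record(worker_id=f"w{i}") for i in range(4)]
    rows[2]["pcs_score"] = np.nan
    cohort = pd.DataFrame(rows)
    profiles, excluded = rs.classify_cohort(cohort)
    assert len(profiles) == 3
    assert len(excluded) == 1
    assert excluded.iloc[0]["worker_id"] == "w2"
    assert "pcs_score" in excluded.iloc[0]["missing_fields"]


def test_threshold_flip_changes_exactly_one_flag():
    """Crossing one instrument's cutoff flips that flag and no other."""
    low = rs.build_risk_profile(_complete_record())
    flips = {
        "psychological_distress": {"k10_score": 22},
        "poor_physical_health": {"pcs_score": 49.9},
        "poor_sleep": {"sleep_hours": 6.9},
        "risky_alcohol": {"auditc_score": 4},
        "smoking": {"smoking_status": "current"},
        "insufficient_pa": {"met_minutes": 599.0},
        "weight_problem": {"weight_kg": 85.0},
        "poor_diet": {"veg_serves": 4.9},
    }
    for cond, override in flips.items():
        high = rs.build_risk_profile(_complete_record(**override))
        assert high.flags[cond] and not low.flags[cond]
        others = [c for c in CONDITIONS if c != cond]
        assert all(high.flags[c] == low.flags[c] for c in others)


def test_prevalence_table_reference_fractions():
    """139/216 flagged -> 64.4%; 19/216 -> 8.8% (reference cohort fractions)."""
    n = 216
    frame = pd.DataFrame(False, index=range(n), columns=list(CONDITIONS))
    frame.loc[:138, "poor_sleep"] = True          # 139 workers
    frame.loc[:18, "poor_physical_health"] = True  # 19 workers
    frame["risk_count"] = frame[list(CONDITIONS)].sum(axis=1)
    table = rs.prevalence_table(frame).set_index("condition")
    assert table.at["poor_sleep", "prevalence_pct"] == pytest.approx(64.35, abs=0.01)
    assert round(table.at["poor_sleep", "prevalence_pct"], 1) == 64.4
    assert round(table.at["poor_physical_health", "prevalence_pct"], 1) == 8.8
    assert table.at["smoking", "prevalence_pct"] == 0.0


def test_prevalence_table_empty_errors():
    with pytest.raises(ValueError):
        rs.prevalence_table(pd.DataFrame(columns=list(CONDITIONS) + ["risk_count"]))
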