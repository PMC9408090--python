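"""Instrument scoring and high/low risk classification.

Eight health conditions are classified high/low risk from raw survey
instruments: psychological distress (K10), poor physical health (SF-8 PCS),
poor sleep (duration + quality), risky alcohol use (AUDIT-C, sex-specific
cut-offs), current smoking, insufficient physical activity (IPAQ
MET-minutes), weight problem (BMI outside the healthy band) and poor diet
(fruit/vegetable servings below guideline minima). A worker's risk count is
the number of flagged conditions; counts are tiered as low (0-2),
medium (3-4) and high (5+).

Every classifier is a pure threshold function and accepts scalars or NumPy
arrays, so whole cohorts are classified vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .reference import CONDITIONS

logger = logging.getLogger(__name__)

#: Sleep-quality levels, best to worst. "Fairly bad" and "very bad" count
#: as poor quality.
SLEEP_QUALITY_LEVELS = ("very good", "good", "fair", "fairly bad", "very bad")
POOR_SLEEP_QUALITY = frozenset({"fairly bad", "very bad"})

SMOKING_LEVELS = ("never", "previous", "current")

#: Standard IPAQ short-form MET weights per activity intensity.
IPAQ_MET_WEIGHTS = {"walking": 3.3, "moderate": 4.0, "vigorous": 8.0}

#: Fields a record must provide for a complete risk profile.
REQUIRED_FIELDS = (
    "gender",
    "k10_score",
    "pcs_score",
    "sleep_hours",
    "sleep_quality",
    "auditc_score",
    "smoking_status",
    "met_minutes",
    "height_m",
    "weight_kg",
    "fruit_serves",
    "veg_serves",
)

TIER_LEVELS = ("low", "medium", "high")


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds defining high risk for each condition.

    Defaults follow the instruments' conventional cut-offs: K10 >= 22,
    SF-8 PCS < 50, sleep < 7 h or poor quality, AUDIT-C >= 4 (men) /
    >= 3 (women), < 600 MET-min/week, BMI outside [18.5, 25), fruit < 2
    or vegetables < 5 serves/day.
    """

    k10_high_min: int = 22
    pcs_high_max: float = 50.0
    sleep_hours_min: float = 7.0
    auditc_high_min_male: int = 4
    auditc_high_min_female: int = 3
    met_min_per_week: float = 600.0
    bmi_low: float = 18.5
    bmi_normal_max: float = 25.0  # exclusive upper edge of the healthy band
    fruit_min: float = 2.0
    veg_min: float = 5.0

    def __post_init__(self) -> None:
        if self.bmi_low >= self.bmi_normal_max:
            raise ValueError("bmi_low must be below bmi_normal_max")
        for name in ("k10_high_min", "sleep_hours_min", "met_min_per_week",
                     "fruit_min", "veg_min", "bmi_low"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


DEFAULT_RULES = ClassificationRules()


@dataclass
class RiskProfile:
    """Per-worker risk flags, count and multiple-risk tier."""

    worker_id: object
    flags: dict[str, bool]
    risk_count: int = field(init=False)
    tier: str = field(init=False)

    def __post_init__(self) -> None:
        missing = set(CONDITIONS) - set(self.flags)
        if missing:
            raise ValueError(f"missing condition flags: {sorted(missing)}")
        self.risk_count = int(sum(bool(self.flags[c]) for c in CONDITIONS))
        self.tier = tier_for_count(self.risk_count)


def tier_for_count(count: int) -> str:
    """Map a risk count (0-8) to the low/medium/high tier."""
    if not 0 <= count <= len(CONDITIONS):
        raise ValueError(f"risk count out of range: {count}")
    if count <= 2:
        return "low"
    if count <= 4:
        return "medium"
    return "high"


def _check_range(x, lo, hi, name):
    x = np.asarray(x, dtype=float)
    if np.any(np.isnan(x)) or np.any(x < lo) or np.any(x > hi):
        raise ValueError(f"{name} must lie in [{lo}, {hi}]")
    return x


def classify_psychological_distress(k10_score, rules: ClassificationRules = DEFAULT_RULES):
    """High risk iff the K10 total (10-50) reaches the high/very-high band."""
    score = _check_range(k10_score, 10, 50, "k10_score")
    out = score >= rules.k10_high_min
    return out if out.ndim else bool(out)


def classify_physical_health(pcs_score, rules: ClassificationRules = DEFAULT_RULES):
    """High risk iff the SF-8 physical component summary is below 50."""
    score = _check_range(pcs_score, 0, 100, "pcs_score")
    out = score < rules.pcs_high_max
    return out if out.ndim else bool(out)


def classify_sleep(sleep_hours, sleep_quality, rules: ClassificationRules = DEFAULT_RULES):
    """High risk iff sleeping under 7 h and/or rating quality fairly/very bad."""
    hours = np.asarray(sleep_hours, dtype=float)
    if np.any(np.isnan(hours)) or np.any(hours < 0):
        raise ValueError("sleep_hours must be non-negative")
    quality = np.asarray(sleep_quality, dtype=object)
    known = np.isin(quality, SLEEP_QUALITY_LEVELS)
    if not np.all(known):
        bad = np.unique(quality[~known])
        raise ValueError(f"unknown sleep quality level(s): {list(bad)}")
    poor_quality = np.isin(quality, list(POOR_SLEEP_QUALITY))
    out = (hours < rules.sleep_hours_min) | poor_quality
    return out if out.ndim else bool(out)


def classify_alcohol(auditc_score, gender, rules: ClassificationRules = DEFAULT_RULES):
    """High risk iff AUDIT-C >= 4 for men, >= 3 for women."""
    score = _check_range(auditc_score, 0, 12, "auditc_score")
    gender = np.asarray(gender, dtype=object)
    known = np.isin(gender, ["male", "female"])
    if not np.all(known):
        raise ValueError(f"unknown gender value(s): {list(np.unique(gender[~known]))}")
    threshold = np.where(gender == "male",
                         rules.auditc_high_min_male, rules.auditc_high_min_female)
    out = score >= threshold
    return out if out.ndim else bool(out)


def classify_smoking(smoking_status):
    """High risk iff currently smoking (never/previous smokers are low risk)."""
    status = np.asarray(smoking_status, dtype=object)
    known = np.isin(status, SMOKING_LEVELS)
    if not np.all(known):
        raise ValueError(f"unknown smoking status: {list(np.unique(status[~known]))}")
    out = status == "current"
    return out if out.ndim else bool(out)


def ipaq_met_minutes(activities) -> float:
    """Weekly IPAQ MET-minutes: sum of MET weight x days/week x minutes/day.

    ``activities`` is an iterable of ``(intensity, days_per_week,
    minutes_per_day)`` tuples with intensity in {walking, moderate,
    vigorous}.
    """
    total = 0.0
    for intensity, days, minutes in activities:
        if intensity not in IPAQ_MET_WEIGHTS:
            raise ValueError(f"unknown activity intensity: {intensity!r}")
        if not 0 <= days <= 7:
            raise ValueError("days per week must lie in [0, 7]")
        if minutes < 0:
            raise ValueError("minutes per day must be non-negative")
        total += IPAQ_MET_WEIGHTS[intensity] * days * minutes
    return total


def classify_physical_activity(met_minutes, rules: ClassificationRules = DEFAULT_RULES):
    """High risk iff below 600 MET-minutes per week."""
    met = np.asarray(met_minutes, dtype=float)
    if np.any(np.isnan(met)) or np.any(met < 0):
        raise ValueError("met_minutes must be non-negative")
    out = met < rules.met_min_per_week
    return out if out.ndim else bool(out)


def bmi(weight_kg, height_m):
    """Body mass index, kg/m^2."""
    weight = np.asarray(weight_kg, dtype=float)
    height = np.asarray(height_m, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be strictly positive")
    out = weight / height**2
    return out if out.ndim else float(out)


def classify_weight(bmi_value, rules: ClassificationRules = DEFAULT_RULES):
    """High risk iff BMI is outside the healthy band [18.5, 25)."""
    b = np.asarray(bmi_value, dtype=float)
    if np.any(b <= 0):
        raise ValueError("BMI must be strictly positive")
    out = (b < rules.bmi_low) | (b >= rules.bmi_normal_max)
    return out if out.ndim else bool(out)


def classify_diet(fruit_serves, veg_serves, rules: ClassificationRules = DEFAULT_RULES):
    """High risk iff fruit < 2 serves/day and/or vegetables < 5 serves/day."""
    fruit = np.asarray(fruit_serves, dtype=float)
    veg = np.asarray(veg_serves, dtype=float)
    if np.any(fruit < 0) or np.any(veg < 0):
        raise ValueError("servings must be non-negative")
    out = (fruit < rules.fruit_min) | (veg < rules.veg_min)
    return out if out.ndim else bool(out)


def build_risk_profile(record, rules: ClassificationRules = DEFAULT_RULES) -> RiskProfile:
    """Classify all eight conditions for one worker record.

    ``record`` is any mapping (dict, pandas Series) with the fields in
    :data:`REQUIRED_FIELDS`. Missing or null instrument fields raise
    ``IncompleteRecordError`` so callers can apply complete-case exclusion.
    """
    missing = [f for f in REQUIRED_FIELDS
               if f not in record or pd.isna(record[f])]
    if missing:
        raise IncompleteRecordError(record.get("worker_id"), missing)
    flags = {
        "poor_sleep": bool(classify_sleep(record["sleep_hours"], record["sleep_quality"], rules)),
        "risky_alcohol": bool(classify_alcohol(record["auditc_score"], record["gender"], rules)),
        "smoking": bool(classify_smoking(record["smoking_status"])),
        "poor_diet": bool(classify_diet(record["fruit_serves"], record["veg_serves"], rules)),
        "weight_problem": bool(classify_weight(bmi(record["weight_kg"], record["height_m"]), rules)),
        "insufficient_pa": bool(classify_physical_activity(record["met_minutes"], rules)),
        "poor_physical_health": bool(classify_physical_health(record["pcs_score"], rules)),
        "psychological_distress": bool(classify_psychological_distress(record["k10_score"], rules)),
    }
    return RiskProfile(worker_id=record.get("worker_id"), flags=flags)


class IncompleteRecordError(ValueError):
    """A worker record lacks instrument fields needed for classification."""

    def __init__(self, worker_id, missing_fields):
        self.worker_id = worker_id
        self.missing_fields = list(missing_fields)
        super().__init__(
            f"worker {worker_id!r} missing fields: {self.missing_fields}")


def classify_cohort(cohort: pd.DataFrame,
                    rules: ClassificationRules = DEFAULT_RULES,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify a whole cohort, excluding incomplete records.

    Returns ``(profiles, excluded)``: ``profiles`` indexed like the complete
    rows of ``cohort`` with one boolean column per condition plus
    ``risk_count`` and ``tier``; ``excluded`` lists dropped worker ids and
    their missing fields (complete-case rule).
    """
    present = [f for f in REQUIRED_FIELDS if f in cohort.columns]
    absent = [f for f in REQUIRED_FIELDS if f not in cohort.columns]
    mask_complete = cohort[present].notna().all(axis=1) if present else pd.Series(False, index=cohort.index)
    if absent:
        mask_complete[:] = False
    excluded_rows = cohort.loc[~mask_complete]
    excluded = pd.DataFrame({
        "worker_id": excluded_rows.get("worker_id", excluded_rows.index),
        "missing_fields": [
            absent + [f for f in present if pd.isna(row[f])]
            for _, row in excluded_rows.iterrows()
        ],
    })
    if len(excluded):
        logger.info("complete-case exclusion: %d record(s) dropped", len(excluded))
    df = cohort.loc[mask_complete]
    if df.empty:
        return (pd.DataFrame(columns=list(CONDITIONS) + ["risk_count", "tier"]),
                excluded)

    profiles = pd.DataFrame(index=df.index)
    profiles["worker_id"] = df.get("worker_id", df.index)
    profiles["poor_sleep"] = classify_sleep(df["sleep_hours"].to_numpy(),
                                            df["sleep_quality"].to_numpy(), rules)
    profiles["risky_alcohol"] = classify_alcohol(df["auditc_score"].to_numpy(),
                                                 df["gender"].to_numpy(), rules)
    profiles["smoking"] = classify_smoking(df["smoking_status"].to_numpy())
    profiles["poor_diet"] = classify_diet(df["fruit_serves"].to_numpy(),
                                          df["veg_serves"].to_numpy(), rules)
    profiles["weight_problem"] = classify_weight(
        bmi(df["weight_kg"].to_numpy(), df["height_m"].to_numpy()), rules)
    profiles["insufficient_pa"] = classify_physical_activity(
        df["met_minutes"].to_numpy(), rules)
    profiles["poor_physical_health"] = classify_physical_health(
        df["pcs_score"].to_numpy(), rules)
    profiles["psychological_distress"] = classify_psychological_distress(
        df["k10_score"].to_numpy(), rules)
    profiles["risk_count"] = profiles[list(CONDITIONS)].sum(axis=1).astype(int)
    profiles["tier"] = pd.cut(profiles["risk_count"], bins=[-1, 2, 4, 8],
                              labels=TIER_LEVELS).astype(str)
    return profiles, excluded


def prevalence_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-condition prevalence (%) and risk-count distribution.

    ``profiles`` is the frame returned by :func:`classify_cohort` (or any
    frame with the eight condition columns and ``risk_count``).
    """
    if profiles.empty:
        raise ValueError("cannot summarise an empty set of risk profiles")
    n = len(profiles)
    rows = [{"condition": c,
             "n_high_risk": int(profiles[c].sum()),
             "prevalence_pct": 100.0 * profiles[c].sum() / n}
            for c in CONDITIONS]
    table = pd.DataFrame(rows)
    counts = profiles["risk_count"].value_counts().reindex(range(9), fill_value=0)
    table.attrs["risk_count_histogram"] = counts.to_dict()
    table.attrs["n"] = n
    return table
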