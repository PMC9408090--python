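"""Reference estimates from a published cross-sectional survey of 216
Australian FIFO mining workers.

These are the printed inputs that the costing consistency checks
(:func:`fifocost.report.golden_tables_check`) recompute from: high/low
group means and excess losses per health condition, covariate-adjusted
excess-loss coefficients, condition prevalences, and the published
aggregate cost figures. They also supply the default margins for the
synthetic cohort generator (condition prevalences, demographic mix,
zero-loss fractions).

All monetary values are Australian dollars per year; loss measures are
percentages of scheduled work time.
"""

from __future__ import annotations

# Human-capital salary assumption: average weekly mining earnings (May 2021)
# times 48 working weeks.
ANNUAL_SALARY_AUD = 134_323.20
WORKING_WEEKS_PER_YEAR = 48
WEEKLY_EARNINGS_AUD = ANNUAL_SALARY_AUD / WORKING_WEEKS_PER_YEAR

N_WORKERS = 216

#: Canonical order of the eight health conditions.
CONDITIONS = (
    "poor_sleep",
    "risky_alcohol",
    "smoking",
    "poor_diet",
    "weight_problem",
    "insufficient_pa",
    "poor_physical_health",
    "psychological_distress",
)

CONDITION_LABELS = {
    "poor_sleep": "Poor sleep condition",
    "risky_alcohol": "Risky alcohol use",
    "smoking": "Smoking",
    "poor_diet": "Poor diet",
    "weight_problem": "Weight problems",
    "insufficient_pa": "Insufficient physical activity",
    "poor_physical_health": "Poor physical health",
    "psychological_distress": "Psychological distress",
}

#: Loss measures in canonical order.
MEASURES = ("absenteeism", "presenteeism", "total")

#: High-risk prevalence (%) per condition in the reference cohort.
PREVALENCE_PCT = {
    "poor_sleep": 64.4,
    "risky_alcohol": 34.3,
    "smoking": 26.4,
    "poor_diet": 96.3,
    "weight_problem": 74.5,
    "insufficient_pa": 26.9,
    "poor_physical_health": 8.8,
    "psychological_distress": 33.3,
}

#: Distribution of the number of co-occurring conditions (%).
RISK_COUNT_DISTRIBUTION_PCT = {1: 2.3, 2: 18.1, 3: 31.0, 4: 24.5, "5+": 24.1}

# Zero-inflation margins of the loss measures (4-week recall).
ANY_ABSENTEEISM_PCT = 20.4
ANY_PRESENTEEISM_PCT = 53.7
HOURS_MISSED_4W_MEAN = 16.07
HOURS_MISSED_4W_SD = 20.34
HOURS_MISSED_4W_RANGE = (1.0, 96.0)
MEAN_ABSENTEEISM_PCT = 1.70
MEAN_PRESENTEEISM_PCT = 3.84
MEAN_TOTAL_LOSS_PCT = 7.48
#: Impairment-rating bins among all workers (%): rating 0, 1-2, 3-4, >=5.
IMPAIRMENT_BIN_PCT = {"0": 46.3, "1-2": 29.6, "3-4": 14.8, "5+": 9.3}

# ---------------------------------------------------------------------------
# Unadjusted high/low group comparison, per worker
# (condition, measure) -> (mean_high %, mean_low %, excess %, cost AUD/yr, stars)
# ---------------------------------------------------------------------------
UNADJUSTED_EXCESS = {
    ("poor_sleep", "absenteeism"): (2.07, 1.04, 1.03, 1383.53, ""),
    ("poor_sleep", "presenteeism"): (4.64, 2.40, 2.24, 3008.84, "**"),
    ("poor_sleep", "total"): (6.43, 3.36, 3.07, 4123.72, "*"),
    ("risky_alcohol", "absenteeism"): (1.75, 1.68, 0.07, 94.03, ""),
    ("risky_alcohol", "presenteeism"): (4.12, 3.70, 0.42, 564.16, ""),
    ("risky_alcohol", "total"): (5.71, 5.14, 0.57, 765.64, ""),
    ("smoking", "absenteeism"): (1.99, 1.60, 0.39, 523.86, ""),
    ("smoking", "presenteeism"): (5.70, 3.18, 2.52, 3384.94, "**"),
    ("smoking", "total"): (7.37, 4.61, 2.77, 3720.75, "*"),
    ("poor_diet", "absenteeism"): (1.77, 0.07, 1.70, 2283.49, ""),
    ("poor_diet", "presenteeism"): (3.92, 1.88, 2.04, 2740.19, ""),
    ("poor_diet", "total"): (5.47, 1.94, 3.53, 4741.61, ""),
    ("weight_problem", "absenteeism"): (1.77, 1.51, 0.26, 349.24, ""),
    ("weight_problem", "presenteeism"): (4.02, 3.32, 0.70, 940.26, ""),
    ("weight_problem", "total"): (5.56, 4.69, 0.86, 1155.18, ""),
    ("insufficient_pa", "absenteeism"): (2.73, 1.32, 1.41, 1893.96, "*"),
    ("insufficient_pa", "presenteeism"): (5.13, 3.37, 1.76, 2364.09, ""),
    ("insufficient_pa", "total"): (7.52, 4.54, 2.98, 4002.83, "*"),
    ("poor_physical_health", "absenteeism"): (4.23, 1.46, 2.77, 3720.75, "*"),
    ("poor_physical_health", "presenteeism"): (11.71, 3.08, 8.63, 11592.09, "***"),
    ("poor_physical_health", "total"): (15.11, 4.40, 10.71, 14386.01, "***"),
    ("psychological_distress", "absenteeism"): (3.08, 1.01, 2.07, 2789.49, "**"),
    ("psychological_distress", "presenteeism"): (7.01, 2.26, 4.75, 6380.35, "***"),
    ("psychological_distress", "total"): (9.64, 3.19, 6.45, 8663.85, "***"),
}

#: Cells of the published per-worker table whose printed cost is consistent
#: only with the *unrounded* high-low group difference, not with the printed
#: excess column (2789.49 / 1343.232 = 2.0767%, vs printed excess 2.07%).
#: The audit validates these under the rounding-propagation bound of the
#: group means printed at 2 dp (a half-ULP each), not the 0.5 AUD band.
PRINT_ERRATA = {("psychological_distress", "absenteeism")}

#: Published mean per-worker annual cost over the eight conditions (AUD).
PER_WORKER_COST_MEANS = {
    "absenteeism": 1629.79,
    "presenteeism": 3871.87,
    "total": 5194.95,
}

# ---------------------------------------------------------------------------
# Covariate-adjusted excess loss and cost per 1000 workers
# (condition, measure) -> (adjusted excess %, cost AUD/yr/1000 workers or None,
#                          stars). Smoking recorded no excess absenteeism
# (negative coefficient), so its absenteeism cost is not applicable.
# ---------------------------------------------------------------------------
ADJUSTED_PER_1000 = {
    ("poor_sleep", "absenteeism"): (1.41, 1219708.39, ""),
    ("poor_sleep", "presenteeism"): (2.17, 1877139.86, "*"),
    ("poor_sleep", "total"): (3.28, 2837335.82, "*"),
    ("risky_alcohol", "absenteeism"): (0.93, 428477.58, ""),
    ("risky_alcohol", "presenteeism"): (1.48, 681878.29, ""),
    ("risky_alcohol", "total"): (2.26, 1041246.58, ""),
    ("smoking", "absenteeism"): (-0.07, None, ""),
    ("smoking", "presenteeism"): (1.26, 446812.69, ""),
    ("smoking", "total"): (1.03, 365251.65, ""),
    ("poor_diet", "absenteeism"): (3.20, 4139303.73, ""),
    ("poor_diet", "presenteeism"): (4.26, 5510448.09, "*"),
    ("poor_diet", "total"): (6.85, 8860697.05, "*"),
    ("weight_problem", "absenteeism"): (1.00, 1000707.84, ""),
    ("weight_problem", "presenteeism"): (1.50, 1501061.76, ""),
    ("weight_problem", "total"): (2.21, 2211564.33, ""),
    ("insufficient_pa", "absenteeism"): (1.64, 592580.23, ""),
    ("insufficient_pa", "presenteeism"): (2.54, 917776.70, "**"),
    ("insufficient_pa", "total"): (3.88, 1401958.10, "**"),
    ("poor_physical_health", "absenteeism"): (2.79, 329790.32, ""),
    ("poor_physical_health", "presenteeism"): (9.05, 1069749.96, "***"),
    ("poor_physical_health", "total"): (11.10, 1312069.02, "***"),
    ("psychological_distress", "absenteeism"): (2.47, 1104821.75, "*"),
    ("psychological_distress", "presenteeism"): (4.64, 2075454.63, "***"),
    ("psychological_distress", "total"): (6.56, 2934263.44, "***"),
}

#: Published annual cost totals per 1000 workers (AUD). Absenteeism sums the
#: seven conditions with positive adjusted excess (smoking excluded).
PER_1000_TOTALS = {
    "absenteeism": 8_815_389.84,
    "presenteeism": 14_080_321.98,
    "total": 20_964_385.99,
}

#: Published mean annual cost per 1000 workers over contributing conditions.
PER_1000_MEANS = {
    "absenteeism": 1_259_341.41,
    "presenteeism": 1_760_040.25,
    "total": 2_620_548.25,
}

#: Published 95% certainty intervals from the probabilistic sensitivity
#: analysis (millions of AUD).
PSA_CERTAINTY_INTERVALS_M = {
    "absenteeism": (8.81, 8.83),
    "presenteeism": (14.07, 14.10),
    "total": (20.95, 20.99),
}

# ---------------------------------------------------------------------------
# Demographic and work-characteristic margins of the reference cohort,
# used as sampling weights by the synthetic generator.
# ---------------------------------------------------------------------------
GENDER_PCT = {"male": 66.2, "female": 33.8}
AGE_MEAN, AGE_SD = 39.9, 11.6
FIFO_ROLE_PCT = {
    "management": 25.0,
    "professional": 12.5,
    "maintenance": 18.1,
    "production": 20.8,
    "operator": 16.2,
    "catering": 4.6,
    "other": 2.8,
}
SHIFT_PATTERN_PCT = {"rotation": 57.4, "regular": 42.6}
SHIFT_HOURS_MEAN, SHIFT_HOURS_SD = 11.9, 1.7
DAYS_ON_PCT = {"<8": 19.9, "8-14": 72.2, "15+": 7.9}
DAYS_OFF_PCT = {"<8": 86.6, "8-14": 13.4}
FIFO_YEARS_PCT = {"<5": 40.3, "5-9": 21.3, "10+": 38.4}
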