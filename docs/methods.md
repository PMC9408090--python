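# Methods

## Scope and data model

`fifocost` prices health-related productivity loss in a FIFO mining
workforce from worker-level survey records. A record carries demographics
and work characteristics (age, gender, FIFO role, shift pattern and hours,
days on/off, years in FIFO), raw health-instrument responses (K10, SF-8
PCS, sleep duration and quality, AUDIT-C, smoking status, IPAQ MET-minutes
or activity items, height/weight, fruit/vegetable servings) and the three
WPAI-GH items over a 4-week recall (hours missed, hours worked, 0–10
impairment rating). Records missing any instrument field are excluded
complete-case, with the count logged and reported in the run manifest;
workers with zero missed and zero worked hours have undefined loss and are
likewise excluded with a logged reason.

## Risk classification

Each classifier is a deterministic threshold function (see the README for
the cut-offs); boundary semantics follow the instruments' conventions:
K10 ≥ 22 flags distress, PCS < 50 flags poor physical health, 600
MET-minutes exactly meets the activity guideline, BMI uses the half-open
healthy band [18.5, 25) so the bands are exhaustive and non-overlapping.
Sleep quality is a 5-level ordinal (very good … very bad) with the worst
two levels counting as poor. The tier map over risk counts (low 0–2,
medium 3–4, high 5+) is total by construction and exhaustively tested
over all 2⁸ flag combinations.

## WPAI-GH scoring

Items recalled over 4 weeks are divided by 4 before scoring. Total loss is
computed on the fraction scale, `a + (1 − a)·p`, and reported as a
percentage, which keeps every output in [0, 100] and makes the identity
and cap properties exact (`total = p` when `a = 0`; `total = 100` when
`a = 100`). All values are carried at full precision and rounded only in
report rendering (2 dp). Scoring is validated against an exact
rational-arithmetic oracle to 1e-12 on 10⁴ random item sets.

## Costing

Currency arithmetic is ordinary floating point, reported to 2 dp; the
audit of printed reference cells uses integer-cent and `Fraction`
arithmetic so "to the cent" comparisons are exact. A condition with a
negative adjusted excess contributes no cost: its per-1000 cost is
recorded as not applicable and it is excluded from the column total and
from the mean's denominator (in the bundled reference table this affects
smoking for absenteeism, leaving 7 contributing conditions there and 8
elsewhere).

One cell of the bundled per-worker reference table is an erratum in the
published source: the psychological-distress absenteeism cost (2789.49)
equals the salary times an unrounded group-mean difference of 2.0767%,
not the printed excess of 2.07% (which gives 2780.49). The consistency
audit therefore checks that cell under the deterministic
rounding-propagation bound of its 2-dp inputs (0.01% of salary, 13.43 AUD)
rather than the 0.5 AUD band used for the other 23 cells; the erratum is
recorded in `fifocost.reference.PRINT_ERRATA`.

## Inference

Loss measures are zero-inflated and right-skewed, so group contrasts are
nonparametric. Mann–Whitney uses average ranks with tie-corrected
variance; the reported deviate is signed so that z < 0 when the high-risk
group is stochastically larger (the reporting convention of the reference
tables). Its p-value is computed by exhaustive enumeration over group
assignments (conditional on the pooled values, so ties are handled) for
pooled n ≤ 12, and by the normal approximation otherwise. Kruskal–Wallis
uses the tie-corrected H with a χ² reference; Dunn's post hoc compares
mean ranks with the tie-corrected pooled variance and multiplies p by the
number of pairs (capped at 1). All tests are two-sided at α = 0.05.

The adjusted excess-loss model is OLS of a loss percentage on age, gender,
FIFO role (7 levels, management reference), shift pattern, shift hours,
days on/off, years in FIFO, the eight condition flags, and the
multiple-risk tier as medium/high dummies. The tier is a threshold
function of the flag sum, so it is strongly — though not linearly —
related to the flags; the VIF output surfaces the resulting inflation, and
exact rank deficiency raises an error naming the collinear columns.
Outcomes are modelled on the raw percentage scale; part 2 of the two-part
model optionally log-transforms positive losses, but the default is the
raw scale. The two-part model fits a logistic any-loss model on the full
sample (odds ratios with Wald 95% CIs, McFadden pseudo-R²) and OLS on the
positive subsample; near-boundary fitted probabilities are flagged as
possible separation. VIFs are 1/(1 − R²ⱼ) from regressing each design
column on the others, with perfectly explained columns flagged infinite.

## Synthetic cohort generator

The generator defines the study conditions under which the estimators are
tested; it is not fitted to any worker-level data.

* **Flags.** The eight condition indicators come from a latent Gaussian
  copula with equicorrelation 0.2 (co-occurrence is observed in such
  cohorts but no correlation structure is published; 0.2 yields risk-count
  dispersion of the right order). Thresholds are set at Φ⁻¹(1 − pⱼ) so
  marginal prevalences equal the configured targets, which default to the
  reference cohort's values (poor diet 96.3% … poor physical health 8.8%).
* **Instruments.** Raw responses are drawn backwards from the intended
  flag (e.g. K10 uniform on 22–50 when flagged, 10–21 otherwise), with
  margins kept clear of classifier boundaries so the classifiers must
  reproduce the intended flags for 100% of workers — exercising
  `risk_scoring` end to end rather than short-circuiting it.
* **Losses.** Any-loss indicators follow logistic hurdles in the flags.
  Default intercepts (−2.8102 absenteeism, −1.3334 presenteeism) were
  calibrated once by root-finding over 800k latent draws so the default
  configuration yields the reference margins of 20.4% any-absenteeism and
  53.7% any-presenteeism; with all effects zero the zero fraction is
  exactly 1 − logistic(intercept), which is tested analytically. Positive
  absenteeism is a base percentage from lognormal 4-week hours (μ=2.3,
  σ=1.0 on the log scale, truncated to [1 h, 96 h]; mean ≈ 16 h,
  SD ≈ 20 h) over a 168-h contract (12 h × 14 days on per 28-day cycle),
  plus additive per-condition shifts — linear in the flags, so a correctly
  implemented two-part model recovers the shifts as n grows. The
  impairment rating is a latent 1 + Gamma(1.2, 0.8) score plus shifts and
  Gaussian noise (SD 0.8), rounded and clamped to 1–10, giving the
  concentrated 1–4 shape with a tail seen in such cohorts.
* **Demographics** are sampled independently from the reference margins;
  no demographic–risk correlation is induced by default.

Default per-condition effect sizes are design choices, strongest for poor
physical health and psychological distress in line with the predictor
pattern of the reference study. With ratings scored as rating × 10, the
generator's mean presenteeism (~15%) is higher than the reference
cohort's printed mean rate — the published rate table is consistent with
an additional division of the rating by 4 that the scoring contract here
deliberately does not apply — so the generator targets the zero fractions
and rating-bin shape, not the printed mean percentages.

What passing tests show, and do not show: calibration, recovery and
coverage results demonstrate that the estimators are implemented correctly
under the generator's assumptions (logistic hurdle, additive positive
part, copula-correlated flags, no demographic confounding). Real cohorts
can violate all of these — nonresponse, reporting bias, demographic–risk
correlation, non-additive effects — and nothing here validates the
pipeline against such violations.

## Monte-Carlo PSA

Adjusted excess coefficients are resampled normal(point, SE) and
prevalences from a moment-matched beta (conventional choices for
regression estimates and proportions); the salary is held fixed. Each of
the default 1000 draws is pushed through the same costing formulas and
totals are summarised by the mean and percentile 2.5/97.5 interval.
Negative excess draws are retained by default so the Monte-Carlo mean is
an unbiased estimate of the deterministic total (clamping at zero is
available but biases the mean upward, and its use is logged). The input
SEs are user configuration: the published certainty intervals were
produced from unpublished SEs and are not reproduced here.

## Problem sizes and numerical choices

The test suite exercises calibration and recovery at n = 50,000 workers
(marginal prevalences within 1 pp; two-part recovery using the median
estimate over five cohorts within two median SEs, which damps the ~5%
per-parameter false-failure rate of a single-draw 2-SE check across 16
parameters), CI coverage pooled over 500 seeds at n = 1000 (the
asymptotic regime of the OLS intervals), enumeration oracles at pooled
n ≤ 8, and reference-cohort margins at n = 216 within binomial sampling
bands. Rank-test p-values switch from enumeration to the normal
approximation above pooled n = 12. Degenerate inputs (identical groups,
all-zero or all-positive outcomes, empty cohorts, zero-variance columns)
raise informative errors or return the exact limiting values (p = 1,
H = 0) rather than NaNs.

## Known limitations

* Cross-sectional costing: the human-capital approach prices gross wage
  time and ignores friction costs, team spillovers and wage heterogeneity
  across roles.
* SF-8 PCS is accepted only as a precomputed score (the norm-based item
  weights are proprietary); K10 is accepted as a score or as item
  responses summed 10–50.
* The adjusted model treats the loss percentage as linear in covariates
  despite the zero mass; the two-part model is the preferred predictor
  analysis, and the adjusted coefficients serve the costing convention.
* Printed reference values carry 1–2 dp rounding; audits therefore use
  the stated tolerances (0.5 AUD per worker, 0.01% relative per 1000)
  rather than exact equality, except where integer-cent sums are exact.
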