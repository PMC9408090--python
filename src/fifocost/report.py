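"""End-to-end pipeline driver, report tables and golden consistency checks.

:func:`run_pipeline` takes a cohort (CSV or generator config) through risk
classification, WPAI scoring, unadjusted and adjusted costing, tier
comparisons, two-part predictor models and the PSA, writing each report
table as CSV plus a human-readable text rendering and a JSON run manifest.

:func:`golden_tables_check` recomputes every published cost figure from its
printed inputs (excess losses, prevalences, the salary assumption) through
the costing formulas and compares against the printed outputs — a
desk-scale audit of the package's cost arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .costing import (DEFAULT_SALARY, SalaryModel, aggregate_costs,
                      cost_per_1000, cost_per_worker, excess_loss)
from .inference import (dunn_bonferroni, fit_adjusted_excess, fit_two_part,
                        kruskal_wallis, mann_whitney)
from .psa import ParameterSpec, PSAConfig, export_scatter, run_psa
from .reference import CONDITIONS, MEASURES
from .risk_scoring import ClassificationRules, DEFAULT_RULES, classify_cohort, prevalence_table
from .synthetic_cohort import GeneratorConfig, RECORD_COLUMNS, generate_cohort
from .wpai_scoring import score_cohort

logger = logging.getLogger(__name__)

_MEASURE_COLUMN = {"absenteeism": "absenteeism_pct",
                   "presenteeism": "presenteeism_pct",
                   "total": "total_loss_pct"}

_NUMERIC_BOUNDS = {
    "k10_score": (10, 50),
    "pcs_score": (0, 100),
    "auditc_score": (0, 12),
    "wpai_impairment_0_10": (0, 10),
}
_NON_NEGATIVE = ("sleep_hours", "met_minutes", "fruit_serves", "veg_serves",
                 "wpai_hours_missed_4w", "wpai_hours_worked_4w")


def significance_stars(p: float) -> str:
    """Footnote stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


class SchemaError(ValueError):
    """A cohort CSV violates the worker-record schema."""


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a worker-level cohort CSV.

    Violations are reported with row and column context; rows with missing
    instrument fields are retained here and excluded later by the
    complete-case rule.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    problems = []
    for col, (lo, hi) in _NUMERIC_BOUNDS.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.notna() & ((vals < lo) | (vals > hi))]
        problems += [f"row {i}, column {col}: value {df.at[i, col]!r} "
                     f"outside [{lo}, {hi}]" for i in bad[:5]]
    for col in _NON_NEGATIVE:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.notna() & (vals < 0)]
        problems += [f"row {i}, column {col}: negative value" for i in bad[:5]]
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as a UTF-8, header-row CSV with the canonical columns."""
    cohort[list(RECORD_COLUMNS)].to_csv(path, index=False)


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one of ``input_csv`` / ``generator``."""

    outdir: str | Path
    input_csv: str | Path | None = None
    generator: GeneratorConfig | None = None
    rules: ClassificationRules = DEFAULT_RULES
    salary: SalaryModel = DEFAULT_SALARY
    psa_n_sims: int = 1000
    psa_excess_se_scale: float = 1.0  # multiplier on regression SEs in the PSA
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError(
                "provide exactly one of input_csv or generator config")


def _loss_summary_frame(summary: dict) -> pd.DataFrame:
    rows = [
        ("any_absenteeism_pct", summary["any_absenteeism_pct"]),
        ("any_presenteeism_pct", summary["any_presenteeism_pct"]),
        ("absenteeism_mean_pct", summary["absenteeism_mean"]),
        ("absenteeism_sd_pct", summary["absenteeism_sd"]),
        ("presenteeism_mean_pct", summary["presenteeism_mean"]),
        ("presenteeism_sd_pct", summary["presenteeism_sd"]),
        ("total_loss_mean_pct", summary["total_loss_mean"]),
        ("total_loss_sd_pct", summary["total_loss_sd"]),
    ]
    return pd.DataFrame(rows, columns=["statistic", "value"])


def unadjusted_excess_table(merged: pd.DataFrame,
                            salary: SalaryModel = DEFAULT_SALARY) -> pd.DataFrame:
    """High/low group means, excess loss and per-worker cost per condition.

    ``merged`` carries the condition flag columns and the three loss
    percentage columns. Group differences get Mann-Whitney z/p and stars.
    """
    rows = []
    for cond in CONDITIONS:
        high_mask = merged[cond].astype(bool)
        for measure, col in _MEASURE_COLUMN.items():
            high = merged.loc[high_mask, col].to_numpy()
            low = merged.loc[~high_mask, col].to_numpy()
            if high.size == 0 or low.size == 0:
                rows.append({"condition": cond, "measure": measure,
                             "mean_high": np.nan, "mean_low": np.nan,
                             "excess": np.nan, "cost_per_worker": np.nan,
                             "z": np.nan, "p": np.nan, "stars": ""})
                continue
            exc = excess_loss(high.mean(), low.mean())
            z, p = mann_whitney(high, low, method="asymptotic")
            rows.append({
                "condition": cond, "measure": measure,
                "mean_high": high.mean(), "mean_low": low.mean(),
                "excess": exc, "cost_per_worker": cost_per_worker(exc, salary),
                "z": z, "p": p, "stars": significance_stars(p),
            })
    return pd.DataFrame(rows)


def adjusted_cost_table(merged: pd.DataFrame, prevalences: dict,
                        salary: SalaryModel = DEFAULT_SALARY) -> tuple[pd.DataFrame, dict]:
    """Regression-adjusted excess losses and per-1000-worker costs.

    Returns the cost rows plus the fitted models keyed by measure.
    """
    rows, models = [], {}
    for measure in MEASURES:
        fit = fit_adjusted_excess(merged, _MEASURE_COLUMN[measure])
        models[measure] = fit
        for cond in CONDITIONS:
            coef = fit.condition_excess[cond]
            se = fit.condition_se[cond]
            pval = float(fit.tidy.set_index("term").at[cond, "p"])
            rows.append({
                "condition": cond, "measure": measure,
                "prevalence": prevalences[cond],
                "adjusted_excess": coef, "se": se, "p": pval,
                "stars": significance_stars(pval),
                "cost_per_1000": cost_per_1000(prevalences[cond], coef, salary),
            })
    return pd.DataFrame(rows), models


def tier_comparison(merged: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Loss means by multiple-risk tier with Kruskal-Wallis and Dunn tests."""
    tiers = ("low", "medium", "high")
    mean_rows, test_rows = [], []
    for measure, col in _MEASURE_COLUMN.items():
        groups = [merged.loc[merged["tier"] == t, col].to_numpy() for t in tiers]
        present = [(t, g) for t, g in zip(tiers, groups) if g.size > 0]
        for t, g in present:
            mean_rows.append({"measure": measure, "tier": t,
                              "n": g.size, "mean_pct": g.mean()})
        if len(present) >= 2:
            h, p = kruskal_wallis([g for _, g in present])
            test_rows.append({"measure": measure, "test": "kruskal_wallis",
                              "statistic": h, "p": p,
                              "stars": significance_stars(p)})
            dunn = dunn_bonferroni([g for _, g in present],
                                   labels=[t for t, _ in present])
            for _, r in dunn.iterrows():
                test_rows.append({
                    "measure": measure,
                    "test": f"dunn[{r['group_a']} vs {r['group_b']}]",
                    "statistic": r["z"], "p": r["p_adjusted"],
                    "stars": significance_stars(r["p_adjusted"]),
                })
    return pd.DataFrame(mean_rows), pd.DataFrame(test_rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full costing pipeline and write the report bundle.

    Returns a dict of the report tables (DataFrames), PSA results and the
    manifest. The pipeline is a pure function of (input data, config, seed).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.generator is not None:
        cohort = generate_cohort(config.generator)
        source = {"generator": True, "n_workers": config.generator.n_workers,
                  "generator_seed": config.generator.seed}
    else:
        cohort = read_cohort(config.input_csv)
        source = {"generator": False, "input_csv": str(config.input_csv)}

    profiles, excluded_class = classify_cohort(cohort, config.rules)
    if profiles.empty:
        raise ValueError("no analyzable workers after complete-case exclusion")
    losses, loss_summary, excluded_wpai = score_cohort(cohort.loc[profiles.index])
    keep = profiles.index.intersection(losses.index)
    merged = pd.concat([cohort.loc[keep], profiles.loc[keep].drop(columns="worker_id"),
                        losses.loc[keep].drop(columns="worker_id")], axis=1)

    prev_table = prevalence_table(profiles.loc[keep])
    prevalences = dict(zip(prev_table["condition"], prev_table["prevalence_pct"]))
    loss_frame = _loss_summary_frame(loss_summary)
    unadjusted = unadjusted_excess_table(merged, config.salary)
    adjusted, models = adjusted_cost_table(merged, prevalences, config.salary)
    aggregates = aggregate_costs(adjusted)
    tier_means, tier_tests = tier_comparison(merged)

    # self-audit: every cost in the adjusted table must reproduce from its
    # own prevalence and excess via the costing formula
    for _, row in adjusted.iterrows():
        expected = cost_per_1000(row["prevalence"], row["adjusted_excess"],
                                 config.salary)
        if np.isnan(expected):
            assert np.isnan(row["cost_per_1000"])
        else:
            assert abs(expected - row["cost_per_1000"]) < 1e-6

    two_part = {}
    two_part_notes = {}
    for measure in MEASURES:
        try:
            two_part[measure] = fit_two_part(merged, _MEASURE_COLUMN[measure])
        except ValueError as err:
            two_part_notes[measure] = str(err)

    psa_specs = [
        ParameterSpec(
            condition=r["condition"], measure=r["measure"],
            excess=r["adjusted_excess"],
            excess_se=r["se"] * config.psa_excess_se_scale,
            prevalence=r["prevalence"],
            prevalence_se=100.0 * np.sqrt(
                r["prevalence"] / 100.0 * (1 - r["prevalence"] / 100.0)
                / max(len(merged), 2)),
        )
        for _, r in adjusted.iterrows() if r["adjusted_excess"] > 0
    ]
    psa_results = run_psa(PSAConfig(specs=psa_specs, n_sims=config.psa_n_sims,
                                    seed=config.seed), config.salary)

    # ---- write bundle -----------------------------------------------------
    prev_table.to_csv(outdir / "prevalence.csv", index=False)
    loss_frame.to_csv(outdir / "loss_summary.csv", index=False)
    unadjusted.to_csv(outdir / "unadjusted_excess_costs.csv", index=False)
    adjusted.to_csv(outdir / "adjusted_costs_per_1000.csv", index=False)
    aggregates.to_csv(outdir / "cost_aggregates.csv", index=False)
    tier_means.to_csv(outdir / "tier_means.csv", index=False)
    tier_tests.to_csv(outdir / "tier_tests.csv", index=False)
    for measure, res in two_part.items():
        res.part1.to_csv(outdir / f"two_part_{measure}_logistic.csv", index=False)
        res.part2.to_csv(outdir / f"two_part_{measure}_ols.csv", index=False)
        res.vif.rename_axis("term").reset_index().to_csv(
            outdir / f"two_part_{measure}_vif.csv", index=False)
    psa_summary = {}
    for measure, res in psa_results.items():
        export_scatter(res, outdir / f"psa_{measure}_draws.csv",
                       outdir / f"psa_{measure}_scatter.png"
                       if config.make_plots else None)
        psa_summary[measure] = {"mean": res.mean, "ci95": list(res.ci95),
                                "n_sims": res.n_sims}
    with open(outdir / "psa_summary.json", "w", encoding="utf-8") as fh:
        json.dump(psa_summary, fh, indent=2)

    from . import __version__
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "salary_aud": config.salary.annual_salary,
        **source,
        "n_input": int(len(cohort)),
        "n_analyzed": int(len(merged)),
        "n_excluded_incomplete": int(len(excluded_class)),
        "n_excluded_undefined_loss": int(len(excluded_wpai)),
        "two_part_notes": two_part_notes,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    _write_text_report(outdir, prev_table, loss_frame, unadjusted, adjusted,
                       aggregates, tier_means, tier_tests, psa_summary)

    return {"cohort": cohort, "merged": merged, "prevalence": prev_table,
            "loss_summary": loss_frame, "unadjusted": unadjusted,
            "adjusted": adjusted, "aggregates": aggregates,
            "tier_means": tier_means, "tier_tests": tier_tests,
            "two_part": two_part, "psa": psa_results,
            "models": models, "manifest": manifest}


def _write_text_report(outdir, prev_table, loss_frame, unadjusted, adjusted,
                       aggregates, tier_means, tier_tests, psa_summary) -> None:
    def fmt(df):
        return df.to_string(index=False, float_format=lambda x: f"{x:,.2f}")

    sections = [
        ("Prevalence of high-risk health conditions", fmt(prev_table)),
        ("Productivity loss summary", fmt(loss_frame)),
        ("Unadjusted excess loss and annual cost per worker (AUD)",
         fmt(unadjusted)),
        ("Adjusted excess loss and annual cost per 1000 workers (AUD)",
         fmt(adjusted)),
        ("Cost aggregates", fmt(aggregates)),
        ("Loss by multiple-risk tier", fmt(tier_means)),
        ("Tier comparison tests", fmt(tier_tests)),
        ("PSA summary", json.dumps(psa_summary, indent=2)),
    ]
    text = "\n\n".join(f"== {title} ==\n{body}" for title, body in sections)
    (Path(outdir) / "report.txt").write_text(text + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# golden consistency checks against the published reference tables
# ---------------------------------------------------------------------------

def _cents(x: float) -> int:
    return int(Decimal(str(x)).scaleb(2).to_integral_value(ROUND_HALF_UP))


def _round_half_up(x: Fraction, places: int = 2) -> Decimal:
    return (Decimal(x.numerator) / Decimal(x.denominator)).quantize(
        Decimal(1).scaleb(-places), ROUND_HALF_UP)


def golden_tables_check(salary: SalaryModel = DEFAULT_SALARY) -> pd.DataFrame:
    """Recompute every published cost figure from its printed inputs.

    Per-worker costs must land within 0.5 AUD of the printed cells and
    their column means reproduce the published means exactly at printed
    precision; per-1000 costs within 0.01% relative; column totals
    reproduce the published totals to the cent when summing printed cells.
    Returns one row per check with computed/expected values and a pass flag.
    """
    checks = []

    def add(name, computed, expected, tol, ok=None):
        if ok is None:
            ok = abs(computed - expected) <= tol
        checks.append({"check": name, "computed": computed,
                       "expected": expected, "tolerance": tol, "passed": bool(ok)})

    # per-worker costs from printed excess values; cells listed as print
    # errata are checked under the rounding-propagation bound of the two
    # group means printed at 2 dp (half-ULP each: 0.01% of salary)
    rounding_bound = 0.01 / 100.0 * salary.annual_salary
    for (cond, measure), (_, _, exc, printed_cost, _) in \
            reference.UNADJUSTED_EXCESS.items():
        if (cond, measure) in reference.PRINT_ERRATA:
            add(f"per_worker_rounding[{cond},{measure}]",
                cost_per_worker(exc, salary), printed_cost, rounding_bound)
        else:
            add(f"per_worker[{cond},{measure}]",
                cost_per_worker(exc, salary), printed_cost, 0.5)

    # column means of the printed per-worker cost cells, exact at 2 dp
    for measure, printed_mean in reference.PER_WORKER_COST_MEANS.items():
        cells = [Fraction(_cents(v[3]), 100)
                 for (c, m), v in reference.UNADJUSTED_EXCESS.items()
                 if m == measure]
        mean = sum(cells, Fraction(0)) / len(cells)
        computed = float(_round_half_up(mean))
        add(f"per_worker_mean[{measure}]", computed, printed_mean, 0.0,
            ok=_round_half_up(mean) == Decimal(str(printed_mean)))

    # per-1000 costs from printed prevalence x adjusted excess
    for (cond, measure), (exc, printed_cost, _) in \
            reference.ADJUSTED_PER_1000.items():
        prev = reference.PREVALENCE_PCT[cond]
        computed = cost_per_1000(prev, exc, salary)
        if printed_cost is None:
            add(f"per_1000[{cond},{measure}]", 0.0, 0.0, 0.0,
                ok=np.isnan(computed))
            continue
        add(f"per_1000[{cond},{measure}]", computed, printed_cost,
            1e-4 * printed_cost)

    # column totals and means of printed per-1000 cells, exact in cents
    for measure, printed_total in reference.PER_1000_TOTALS.items():
        cells = [v[1] for (c, m), v in reference.ADJUSTED_PER_1000.items()
                 if m == measure and v[1] is not None and v[0] > 0]
        total_cents = sum(_cents(v) for v in cells)
        add(f"per_1000_total[{measure}]", total_cents / 100.0, printed_total,
            0.0, ok=total_cents == _cents(printed_total))
        mean = Fraction(total_cents, 100 * len(cells))
        printed_mean = reference.PER_1000_MEANS[measure]
        add(f"per_1000_mean[{measure}]", float(_round_half_up(mean)),
            printed_mean, 0.0,
            ok=_round_half_up(mean) == Decimal(str(printed_mean)))

    # aggregate_costs over recomputed rows must agree with printed totals
    rows = pd.DataFrame([
        {"condition": cond, "measure": measure,
         "adjusted_excess": exc,
         "cost_per_1000": cost_per_1000(reference.PREVALENCE_PCT[cond], exc,
                                        salary)}
        for (cond, measure), (exc, _, _) in reference.ADJUSTED_PER_1000.items()
    ])
    agg = aggregate_costs(rows).set_index("measure")
    for measure, printed_total in reference.PER_1000_TOTALS.items():
        add(f"aggregate_recomputed_total[{measure}]",
            float(agg.at[measure, "total_cost_per_1000"]), printed_total,
            1e-4 * printed_total)

    return pd.DataFrame(checks)
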