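"""Human-capital costing of excess productivity loss.

Excess loss for a health condition is the difference in mean productivity
loss between its high- and low-risk groups, either unadjusted (group means)
or covariate-adjusted (a regression coefficient). Costs value that excess
at the gross wage:

* per worker/year:   excess% / 100 x annual salary
* per 1000 workers:  prevalence% / 100 x excess% / 100 x annual salary x 1000

A condition with negative adjusted excess contributes no cost (recorded as
not applicable) and is excluded from totals and means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import ANNUAL_SALARY_AUD, WORKING_WEEKS_PER_YEAR


@dataclass(frozen=True)
class SalaryModel:
    """Annual salary assumption used to monetise lost work time.

    Either pass ``weekly_earnings`` (annualised over ``working_weeks``) or an
    explicit ``annual_salary``. The default is the reference assumption of
    AUD 134,323.20/year (average weekly mining earnings x 48 working weeks).
    """

    weekly_earnings: float | None = None
    working_weeks: int = WORKING_WEEKS_PER_YEAR
    annual_salary: float = ANNUAL_SALARY_AUD

    def __post_init__(self) -> None:
        if self.working_weeks <= 0:
            raise ValueError("working_weeks must be positive")
        if self.weekly_earnings is not None:
            if self.weekly_earnings <= 0:
                raise ValueError("weekly_earnings must be positive")
            object.__setattr__(self, "annual_salary",
                               self.weekly_earnings * self.working_weeks)
        if self.annual_salary <= 0:
            raise ValueError("annual_salary must be positive")


DEFAULT_SALARY = SalaryModel()


def excess_loss(mean_high, mean_low):
    """Excess productivity loss (%): high-risk mean minus low-risk mean."""
    high = np.asarray(mean_high, dtype=float)
    low = np.asarray(mean_low, dtype=float)
    out = high - low
    return out if out.ndim else float(out)


def cost_per_worker(excess, salary: SalaryModel = DEFAULT_SALARY):
    """Annual cost (AUD/worker) of an excess loss percentage."""
    e = np.asarray(excess, dtype=float)
    out = e / 100.0 * salary.annual_salary
    return out if out.ndim else float(out)


def cost_per_1000(prevalence, adjusted_excess,
                  salary: SalaryModel = DEFAULT_SALARY, n_workers: int = 1000):
    """Annual cost (AUD) per ``n_workers`` attributable to one condition.

    ``prevalence`` is the high-risk prevalence (%), ``adjusted_excess`` the
    regression-adjusted excess loss (%). A negative excess returns NaN (cost
    not applicable): such a condition shows no attributable loss.
    """
    prev = np.asarray(prevalence, dtype=float)
    if np.any((prev < 0) | (prev > 100)):
        raise ValueError("prevalence must lie in [0, 100]")
    exc = np.asarray(adjusted_excess, dtype=float)
    out = np.where(exc < 0, np.nan,
                   prev / 100.0 * exc / 100.0 * salary.annual_salary * n_workers)
    return out if out.ndim else float(out)


def aggregate_costs(rows: pd.DataFrame) -> pd.DataFrame:
    """Total and mean annual cost per measure over contributing conditions.

    ``rows`` needs columns ``condition``, ``measure``, ``adjusted_excess``
    and ``cost_per_1000``. Only conditions with positive adjusted excess
    contribute; they define both the total and the mean's denominator.
    Duplicate (condition, measure) pairs are an error.
    """
    required = {"condition", "measure", "adjusted_excess", "cost_per_1000"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"cost rows missing columns: {sorted(missing)}")
    if rows.duplicated(subset=["condition", "measure"]).any():
        dupes = rows.loc[rows.duplicated(subset=["condition", "measure"]),
                         ["condition", "measure"]]
        raise ValueError(f"duplicate cost rows: {dupes.to_dict('records')}")

    out = []
    for measure, grp in rows.groupby("measure", sort=False):
        contributing = grp.loc[grp["adjusted_excess"] > 0]
        costs = contributing["cost_per_1000"].to_numpy(dtype=float)
        total = float(np.nansum(costs))
        n_contrib = int(len(contributing))
        out.append({
            "measure": measure,
            "n_conditions": n_contrib,
            "total_cost_per_1000": total,
            "mean_cost_per_1000": total / n_contrib if n_contrib else 0.0,
        })
    return pd.DataFrame(out)
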