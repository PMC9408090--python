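"""Statistical comparisons and regression models for productivity loss.

Loss distributions are heavily zero-inflated and right-skewed, so group
comparisons are nonparametric (Mann-Whitney, Kruskal-Wallis, Dunn's test
with Bonferroni adjustment) and predictor modelling uses a two-part
(hurdle) approach: a logistic model for any positive loss on the full
sample, then OLS on the positive-loss subsample. Covariate-adjusted excess
losses — the inputs to per-1000-worker costing — come from a linear model
of each loss measure on demographics, work characteristics, the eight
condition flags and the multiple-risk tier.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .reference import CONDITIONS

logger = logging.getLogger(__name__)

#: Continuous work/demographic covariates entered linearly.
CONTINUOUS_COVARIATES = ("age", "shift_hours", "days_on", "days_off", "fifo_years")
#: Categorical covariates dummy-coded against their first (reference) level.
CATEGORICAL_COVARIATES = {
    "gender": "male",
    "fifo_role": "management",
    "shift_pattern": "rotation",
}

_EXACT_MAX_N = 12  # full-enumeration cut-off for the Mann-Whitney p-value


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def mann_whitney(high, low, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney test of high- vs low-risk loss values.

    Returns ``(z, p)`` with the tie-corrected normal-deviate statistic.
    Sign convention: ``z < 0`` when the high-risk group is stochastically
    larger. ``method`` selects the p-value computation: ``"exact"``
    enumerates all group assignments (conditional on the pooled values, so
    ties are handled), ``"asymptotic"`` uses the normal approximation,
    ``"auto"`` picks exact for pooled n <= 12.
    """
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    if high.size == 0 or low.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = high.size, low.size
    pooled = np.concatenate([high, low])
    ranks = stats.rankdata(pooled)
    u_high = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var <= 0:  # all pooled values identical
        return 0.0, 1.0
    z = -(u_high - mu) / math.sqrt(var)

    if method == "auto":
        method = "exact" if n <= _EXACT_MAX_N else "asymptotic"
    if method == "asymptotic":
        p = 2.0 * stats.norm.sf(abs(z))
    elif method == "exact":
        dev_obs = abs(u_high - mu)
        hits = total = 0
        for idx in combinations(range(n), n1):
            u = float(np.sum(ranks[list(idx)])) - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        p = hits / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return z, min(p, 1.0)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p over >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):  # degenerate: no variation at all
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_bonferroni(groups, labels=None) -> pd.DataFrame:
    """Dunn's pairwise mean-rank z tests with Bonferroni adjustment.

    Follows a Kruskal-Wallis test: pooled average ranks, tie-corrected
    pooled variance, two-sided p multiplied by the number of pairs
    (capped at 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    splits = np.cumsum(sizes)[:-1]
    group_ranks = np.split(ranks, splits)
    n = pooled.size
    tie_correction = _tie_term(pooled) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_correction
    m = len(groups) * (len(groups) - 1) // 2

    rows = []
    for (i, ri), (j, rj) in combinations(enumerate(group_ranks), 2):
        diff = ri.mean() - rj.mean()
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = diff / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({
            "group_a": labels[i], "group_b": labels[j], "z": z,
            "p_unadjusted": p_raw, "p_adjusted": min(1.0, p_raw * m),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix rank deficient; collinear columns: "
                         f"{self.columns}")


def build_design(data: pd.DataFrame, include_work: bool = True,
                 include_conditions: bool = True,
                 include_tier: bool = True) -> pd.DataFrame:
    """Assemble the regression design matrix (without intercept).

    ``data`` holds worker covariates merged with condition flags and, if
    ``include_tier``, the ``tier`` column. Categorical covariates are
    dummy-coded against their reference level; the tier enters as medium
    and high dummies against low.
    """
    cols = {}
    if include_work:
        for c in CONTINUOUS_COVARIATES:
            if c in data.columns:
                cols[c] = data[c].astype(float)
        for c, ref in CATEGORICAL_COVARIATES.items():
            if c not in data.columns:
                continue
            for level in sorted(set(data[c].astype(str)) - {ref}):
                cols[f"{c}[{level}]"] = (data[c].astype(str) == level).astype(float)
    if include_conditions:
        for c in CONDITIONS:
            cols[c] = data[c].astype(float)
    if include_tier and "tier" in data.columns:
        for level in ("medium", "high"):
            cols[f"tier[{level}]"] = (data["tier"].astype(str) == level).astype(float)
    X = pd.DataFrame(cols, index=data.index)
    if X.empty:
        raise ValueError("empty design matrix")
    return X


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns not independent of the ones before them (plus intercept)."""
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    names = ["const"] + list(X.columns)
    bad, kept = [], np.ones((len(X), 0))
    for j, name in enumerate(names):
        candidate = np.column_stack([kept, arr[:, j]])
        if np.linalg.matrix_rank(candidate) == kept.shape[1]:
            bad.append(name)
        else:
            kept = candidate
    return bad


# ---------------------------------------------------------------------------
# adjusted excess-loss model
# ---------------------------------------------------------------------------

@dataclass
class AdjustedExcessResult:
    """OLS fit of a loss measure on covariates and condition flags."""

    outcome: str
    tidy: pd.DataFrame           # term, estimate, se, ci_low, ci_high, p
    condition_excess: dict       # condition -> adjusted excess (% points)
    condition_se: dict
    fvalue: float
    f_pvalue: float
    n: int
    model: object = None         # underlying statsmodels result


def fit_adjusted_excess(data: pd.DataFrame, outcome: str,
                        include_work: bool = True,
                        include_tier: bool = True) -> AdjustedExcessResult:
    """Covariate-adjusted excess loss per condition by OLS.

    ``data`` merges losses (``<measure>_pct`` columns), condition flags and
    worker covariates. The eight condition coefficients are the adjusted
    excess losses feeding per-1000-worker costing.
    """
    ycol = outcome if outcome in data.columns else f"{outcome}_pct"
    if ycol not in data.columns:
        raise ValueError(f"outcome column {outcome!r} not found")
    X = build_design(data, include_work=include_work,
                     include_conditions=True, include_tier=include_tier)
    if len(X) <= X.shape[1] + 1:
        raise ValueError("more covariates than observations")
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise RankDeficiencyError(_collinear_columns(X))
    y = data[ycol].astype(float)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    ci = res.conf_int()
    tidy = pd.DataFrame({
        "term": res.params.index,
        "estimate": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "ci_low": ci[0].to_numpy(),
        "ci_high": ci[1].to_numpy(),
        "p": res.pvalues.to_numpy(),
    })
    return AdjustedExcessResult(
        outcome=outcome,
        tidy=tidy,
        condition_excess={c: float(res.params[c]) for c in CONDITIONS},
        condition_se={c: float(res.bse[c]) for c in CONDITIONS},
        fvalue=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        n=int(res.nobs),
        model=res,
    )


# ---------------------------------------------------------------------------
# two-part (hurdle) model
# ---------------------------------------------------------------------------

@dataclass
class TwoPartResult:
    """Logistic any-loss model plus OLS on the positive-loss subsample."""

    outcome: str
    part1: pd.DataFrame          # term, odds_ratio, ci_low, ci_high, p
    part2: pd.DataFrame          # term, estimate, se, ci_low, ci_high, p
    part1_stats: dict            # llf, llnull, pseudo_r2, n
    part2_stats: dict            # fvalue, f_pvalue, adj_r2, n
    vif: pd.Series
    separation_flagged: bool = False
    part1_model: object = None
    part2_model: object = None


def fit_two_part(data: pd.DataFrame, outcome: str,
                 include_work: bool = True, include_tier: bool = False,
                 log_transform_part2: bool = False) -> TwoPartResult:
    """Two-part predictor model of a zero-inflated loss measure.

    Part 1 is a logistic regression of the any-loss indicator on the full
    sample; part 2 an OLS on workers with positive loss (optionally on the
    log scale). Reports odds ratios with 95% CIs, coefficient CIs, fit
    statistics and per-predictor variance inflation factors.
    """
    ycol = outcome if outcome in data.columns else f"{outcome}_pct"
    if ycol not in data.columns:
        raise ValueError(f"outcome column {outcome!r} not found")
    y = data[ycol].astype(float)
    any_loss = (y > 0).astype(float)
    if any_loss.sum() == 0:
        raise ValueError("outcome is zero for every worker; "
                         "the positive part is not estimable")
    if any_loss.sum() == len(any_loss):
        raise ValueError("outcome is positive for every worker; "
                         "the hurdle part is not estimable")

    X = build_design(data, include_work=include_work,
                     include_conditions=True, include_tier=include_tier)
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise RankDeficiencyError(_collinear_columns(X))

    Xc = sm.add_constant(X)
    separation = False
    try:
        logit_res = sm.Logit(any_loss, Xc).fit(disp=0, maxiter=200)
    except Exception:  # pragma: no cover - perfect separation path
        separation = True
        logit_res = sm.Logit(any_loss, Xc).fit_regularized(alpha=1e-6, disp=0)
    fitted = logit_res.predict(Xc)
    if np.any(fitted > 1 - 1e-8) or np.any(fitted < 1e-8):
        separation = True
        logger.warning("possible separation in part-1 logistic model (%s)", outcome)

    ci1 = logit_res.conf_int()
    part1 = pd.DataFrame({
        "term": logit_res.params.index,
        "odds_ratio": np.exp(logit_res.params.to_numpy()),
        "ci_low": np.exp(ci1[0].to_numpy()),
        "ci_high": np.exp(ci1[1].to_numpy()),
        "p": logit_res.pvalues.to_numpy(),
    })
    llnull = float(getattr(logit_res, "llnull", np.nan))
    part1_stats = {
        "llf": float(logit_res.llf),
        "llnull": llnull,
        "pseudo_r2": 1.0 - float(logit_res.llf) / llnull if llnull else np.nan,
        "n": int(len(any_loss)),
    }

    pos = y > 0
    y2 = np.log(y[pos]) if log_transform_part2 else y[pos]
    X2 = sm.add_constant(Xc.loc[pos].drop(columns="const"))
    ols_res = sm.OLS(y2, X2).fit()
    ci2 = ols_res.conf_int()
    part2 = pd.DataFrame({
        "term": ols_res.params.index,
        "estimate": ols_res.params.to_numpy(),
        "se": ols_res.bse.to_numpy(),
        "ci_low": ci2[0].to_numpy(),
        "ci_high": ci2[1].to_numpy(),
        "p": ols_res.pvalues.to_numpy(),
    })
    part2_stats = {
        "fvalue": float(ols_res.fvalue),
        "f_pvalue": float(ols_res.f_pvalue),
        "adj_r2": float(ols_res.rsquared_adj),
        "n": int(ols_res.nobs),
    }
    return TwoPartResult(
        outcome=outcome, part1=part1, part2=part2,
        part1_stats=part1_stats, part2_stats=part2_stats,
        vif=vif(X), separation_flagged=separation,
        part1_model=logit_res, part2_model=ols_res,
    )


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per design column.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing column j on the remaining
    columns (with intercept). A column perfectly explained by the others is
    flagged with ``inf``.
    """
    X = pd.DataFrame(X)
    arr = X.to_numpy(dtype=float)
    n, k = arr.shape
    out = {}
    for j, name in enumerate(X.columns):
        others = np.column_stack([np.ones(n), np.delete(arr, j, axis=1)])
        target = arr[:, j]
        beta, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ beta
        ss_tot = float(np.sum((target - target.mean()) ** 2))
        if ss_tot == 0:  # constant column
            out[name] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        out[name] = np.inf if r2 > 1.0 - 1e-10 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def tidy_to_csv(frame: pd.DataFrame, path) -> None:
    """Write a tidy model table as CSV (stable column order)."""
    frame.to_csv(path, index=False)
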