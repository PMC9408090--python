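"""Rank tests against enumeration oracles; regression models and VIF."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from conftest import merge_cohort
from fifocost import inference as inf
from fifocost.reference import CONDITIONS
from fifocost.synthetic_cohort import GeneratorConfig, generate_cohort


# ---------------------------------------------------------------------------
# enumeration oracles (independent routes: pairwise wins, hand-ranked H)
# ---------------------------------------------------------------------------

def _u_by_pairwise_wins(high, low):
    """U statistic counted directly from pairwise comparisons (no ranks)."""
    u = 0.0
    for h in high:
        for l in low:
            u += 1.0 if h > l else 0.5 if h == l else 0.0
    return u


def oracle_mw_exact_p(high, low):
    """Two-sided permutation p for |U - mu| via exhaustive assignment."""
    pooled = list(high) + list(low)
    n1 = len(high)
    mu = n1 * (len(pooled) - n1) / 2.0
    dev_obs = abs(_u_by_pairwise_wins(high, low) - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(_u_by_pairwise_wins(grp, rest) - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def oracle_kw_h(groups):
    """Tie-corrected Kruskal-Wallis H computed from first principles."""
    pooled = sorted(v for g in groups for v in g)
    n = len(pooled)
    rank_of = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        rank_of[pooled[i]] = (i + 1 + j) / 2.0  # average rank of the tie block
        i = j
    h = 0.0
    for g in groups:
        rsum = sum(rank_of[v] for v in g)
        h += rsum**2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_mann_whitney_identical_groups():
    z, p = inf.mann_whitney([3, 3, 3], [3, 3, 3])
    assert z == 0.0 and p == 1.0


def test_mann_whitney_sign_convention():
    """z < 0 when the high-risk group is stochastically larger."""
    z, _ = inf.mann_whitney([4, 5, 6, 7], [1, 2, 3, 3], method="asymptotic")
    assert z < 0
    z, _ = inf.mann_whitney([1, 2, 3, 3], [4, 5, 6, 7], method="asymptotic")
    assert z > 0


def test_mann_whitney_exact_matches_enumeration_separated_groups():
    high, low = [1, 2, 3], [4, 5, 6]
    _, p = inf.mann_whitney(high, low, method="exact")
    assert p == pytest.approx(oracle_mw_exact_p(high, low))
    assert p == pytest.approx(2 / 20)  # only the two extreme assignments


@pytest.mark.parametrize("seed", range(6))
def test_mann_whitney_exact_matches_enumeration_random(seed):
    rng = np.random.default_rng(seed)
    n1 = int(rng.integers(2, 5))
    n2 = int(rng.integers(2, 9 - n1))
    vals = rng.integers(0, 5, size=n1 + n2)  # small support forces ties
    high, low = vals[:n1], vals[n1:]
    _, p = inf.mann_whitney(high, low, method="exact")
    assert p == pytest.approx(oracle_mw_exact_p(high, low), abs=1e-12)


def test_mann_whitney_exact_agrees_with_scipy_without_ties():
    from scipy.stats import mannwhitneyu
    rng = np.random.default_rng(1)
    for _ in range(5):
        vals = rng.permutation(np.arange(9, dtype=float))
        high, low = vals[:4], vals[4:]
        _, p = inf.mann_whitney(high, low, method="exact")
        ref = mannwhitneyu(high, low, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_mann_whitney_empty_group_errors():
    with pytest.raises(ValueError):
        inf.mann_whitney([], [1, 2])


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn
# ---------------------------------------------------------------------------

def test_kruskal_wallis_identical_groups():
    h, p = inf.kruskal_wallis([[2, 2], [2, 2], [2, 2]])
    assert h == 0.0 and p == 1.0


def test_kruskal_wallis_matches_hand_ranked_oracle():
    groups = [[1, 2], [3, 4], [5, 6]]
    h, _ = inf.kruskal_wallis(groups)
    assert h == pytest.approx(oracle_kw_h(groups))
    rng = np.random.default_rng(2)
    for _ in range(5):
        groups = [list(rng.integers(0, 6, rng.integers(2, 5))) for _ in range(3)]
        h, _ = inf.kruskal_wallis(groups)
        assert h == pytest.approx(oracle_kw_h(groups), abs=1e-10)


def test_kruskal_wallis_errors():
    with pytest.raises(ValueError):
        inf.kruskal_wallis([[1, 2]])
    with pytest.raises(ValueError):
        inf.kruskal_wallis([[1, 2], []])


def test_dunn_identical_groups_all_one():
    table = inf.dunn_bonferroni([[5, 5, 5], [5, 5], [5, 5, 5, 5]])
    assert (table["p_adjusted"] == 1.0).all()


def test_dunn_bonferroni_monotone_and_factor():
    rng = np.random.default_rng(3)
    groups = [rng.normal(m, 1, 12) for m in (0, 0.5, 2.0)]
    table = inf.dunn_bonferroni(groups, labels=["low", "medium", "high"])
    assert len(table) == 3  # k(k-1)/2 pairs
    assert (table["p_adjusted"] >= table["p_unadjusted"] - 1e-15).all()
    expected = np.minimum(1.0, table["p_unadjusted"] * 3)
    np.testing.assert_allclose(table["p_adjusted"], expected)


# ---------------------------------------------------------------------------
# adjusted excess-loss OLS
# ---------------------------------------------------------------------------

def test_adjusted_excess_recovers_known_additive_effects():
    """With a saturated hurdle the loss is linear in the flags; OLS recovers
    the generator's additive increments."""
    cfg = GeneratorConfig(n_workers=20_000, seed=13)
    cfg.hurdle_intercepts = {"absenteeism": 25.0, "presenteeism": -25.0}
    merged = merge_cohort(generate_cohort(cfg))
    fit = inf.fit_adjusted_excess(merged, "absenteeism_pct",
                                  include_work=False, include_tier=False)
    for cond in CONDITIONS:
        truth = cfg.absenteeism_effects[cond][1]
        est, se = fit.condition_excess[cond], fit.condition_se[cond]
        assert abs(est - truth) < 3 * se, cond
    assert fit.fvalue > 0 and fit.n == 20_000


def test_ols_residuals_orthogonal_to_design(merged_216):
    fit = inf.fit_adjusted_excess(merged_216, "total_loss_pct")
    res = fit.model
    X = res.model.exog
    np.testing.assert_allclose(X.T @ res.resid, 0, atol=1e-6)


def test_duplicated_covariate_raises_rank_deficiency(merged_216):
    dup = merged_216.copy()
    dup["poor_sleep"] = dup["age"]  # condition column duplicates a covariate
    with pytest.raises(inf.RankDeficiencyError, match="poor_sleep"):
        inf.fit_adjusted_excess(dup, "total_loss_pct")


def test_adjusted_excess_unknown_outcome(merged_216):
    with pytest.raises(ValueError, match="outcome"):
        inf.fit_adjusted_excess(merged_216, "nonexistent")


# ---------------------------------------------------------------------------
# two-part model and VIF
# ---------------------------------------------------------------------------

def test_two_part_degenerate_outcomes_error(merged_216):
    data = merged_216.copy()
    data["all_zero_pct"] = 0.0
    with pytest.raises(ValueError, match="zero"):
        inf.fit_two_part(data, "all_zero_pct")
    data["all_pos_pct"] = 5.0
    with pytest.raises(ValueError, match="positive"):
        inf.fit_two_part(data, "all_pos_pct")


def test_two_part_or_equals_exp_coefficient(merged_216):
    fit = inf.fit_two_part(merged_216, "presenteeism_pct", include_work=False)
    params = fit.part1_model.params
    np.testing.assert_allclose(fit.part1["odds_ratio"], np.exp(params))
    assert (fit.part1["ci_low"] <= fit.part1["odds_ratio"]).all()
    assert (fit.part1["odds_ratio"] <= fit.part1["ci_high"]).all()
    assert (fit.part1["odds_ratio"] > 0).all()
    assert fit.part2_stats["n"] == int((merged_216["presenteeism_pct"] > 0).sum())


def test_two_part_detects_strong_hurdle_effect():
    """A large poor-physical-health hurdle effect shows as OR > 1 with CI
    excluding 1 at moderate n."""
    merged = merge_cohort(generate_cohort(GeneratorConfig(n_workers=4000, seed=17)))
    fit = inf.fit_two_part(merged, "absenteeism_pct", include_work=False)
    row = fit.part1.set_index("term").loc["poor_physical_health"]
    assert row["odds_ratio"] > 1
    assert row["ci_low"] > 1


def test_vif_orthogonal_columns_one():
    n = 64
    X = pd.DataFrame({
        "a": np.tile([1.0, -1.0], n // 2),
        "b": np.repeat([1.0, -1.0], n // 2),
    })
    v = inf.vif(X)
    np.testing.assert_allclose(v, 1.0, atol=1e-10)


def test_vif_bivariate_closed_form():
    rng = np.random.default_rng(4)
    x = rng.normal(size=20_000)
    y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=20_000)
    v = inf.vif(pd.DataFrame({"x": x, "y": y}))
    r2 = np.corrcoef(x, y)[0, 1] ** 2
    np.testing.assert_allclose(v, 1 / (1 - r2), rtol=1e-6)
    assert v["x"] == pytest.approx(1 / (1 - 0.81), rel=0.05)


def test_vif_duplicate_column_infinite():
    x = np.arange(30, dtype=float)
    v = inf.vif(pd.DataFrame({"x": x, "x2": x}))
    assert np.isinf(v).all()
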