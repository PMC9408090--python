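import pandas as pd
import pytest

from fifocost import risk_scoring, synthetic_cohort, wpai_scoring
from fifocost.synthetic_cohort import GeneratorConfig, generate_cohort


def merge_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort merged with classified flags and scored losses."""
    profiles, _ = risk_scoring.classify_cohort(cohort)
    losses, _, _ = wpai_scoring.score_cohort(cohort.loc[profiles.index])
    keep = profiles.index.intersection(losses.index)
    return pd.concat(
        [cohort.loc[keep],
         profiles.loc[keep].drop(columns="worker_id"),
         losses.loc[keep].drop(columns="worker_id")], axis=1)


def null_generator_config(n_workers: int, seed: int) -> GeneratorConfig:
    """Generator with all condition effects switched off."""
    zero = {c: (0.0, 0.0) for c in synthetic_cohort.CONDITIONS}
    return GeneratorConfig(n_workers=n_workers, seed=seed,
                           absenteeism_effects=dict(zero),
                           presenteeism_effects=dict(zero))


@pytest.fixture(scope="session")
def cohort_216():
    return generate_cohort(GeneratorConfig(n_workers=216, seed=1))


@pytest.fixture(scope="session")
def cohort_50k_with_truth():
    return generate_cohort(GeneratorConfig(n_workers=50_000, seed=7),
                           return_truth=True)


@pytest.fixture(scope="session")
def merged_216(cohort_216):
    return merge_cohort(cohort_216)
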