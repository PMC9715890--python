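import numpy as np
import pandas as pd
import pytest

from nss import (
    BetaBinomParams,
    cohort_from_frame,
    cohort_from_stage_counts,
    fit_mle,
    simulate_cohort,
)
from nss.simulate import (
    ExaminedNodesModel,
    StageConfig,
    SyntheticConfig,
)

# Published per-T-stage (pN0, pN+) counts of the two cohorts the package's
# fixture presets emulate: a large registry extract and an institutional
# series of resected esophageal squamous cell carcinoma.
SEER_COUNTS = {1: (171, 39), 2: (169, 69), 3: (340, 211), 4: (125, 146)}
INSTITUTION_COUNTS = {1: (116, 34), 2: (171, 117), 3: (260, 255), 4: (196, 255)}


@pytest.fixture(scope="session")
def seer_count_cohort():
    return cohort_from_stage_counts(SEER_COUNTS)


@pytest.fixture(scope="session")
def institution_count_cohort():
    return cohort_from_stage_counts(INSTITUTION_COUNTS)


@pytest.fixture()
def tiny_frame():
    """Four valid patients, one per T stage."""
    return pd.DataFrame(
        {
            "patient_id": ["a", "b", "c", "d"],
            "t_stage": [1, 2, 3, 4],
            "nodes_examined": [5, 10, 15, 20],
            "nodes_positive": [0, 1, 3, 0],
            "survival_months": [12.0, 24.0, 6.0, 60.0],
            "event": [0, 1, 1, 0],
        }
    )


def single_stage_config(
    prevalence=0.45,
    alpha=2.0,
    beta=8.0,
    n=2000,
    seed=5,
    t_stage=3,
    convention="unconditional",
):
    return SyntheticConfig(
        stages={t_stage: StageConfig(prevalence, BetaBinomParams(alpha, beta), n)},
        examined=ExaminedNodesModel(family="uniform", lo=5, hi=30),
        seed=seed,
        convention=convention,
    )


@pytest.fixture(scope="session")
def fitted_single_stage():
    """A 2000-patient single-stratum cohort with its truth and fit."""
    config = single_stage_config()
    cohort, truth = simulate_cohort(config)
    fit = fit_mle(cohort.positive_pairs(3), t_stage=3)
    return config, cohort, truth, fit
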