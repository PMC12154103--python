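import numpy as np
import pandas as pd
import pytest

from paxlearn import generate_cohort, preprocess
from paxlearn.synthetic import recovery_config


def aligned_arrays(config, outcome="depression"):
    """Generate a sentinel-free cohort and return model-ready arrays
    aligned row-by-row with the ground truth (no screening applied)."""
    cohort, truth = generate_cohort(config)
    processed = preprocess(cohort, min_age=0)
    assert len(processed.features) == len(cohort)
    X = processed.features.to_numpy(dtype=float)
    y = processed.outcomes[outcome].to_numpy()
    return X, truth.treated, y, truth, processed


@pytest.fixture(scope="session")
def small_cohort():
    """A modest clean cohort under the default study marginals."""
    cohort, truth = generate_cohort(
        __import__("paxlearn").SimulationConfig(n_respondents=4000, seed=11)
    )
    return cohort, truth


@pytest.fixture
def toy_raw_cohort():
    """Six respondents; two carry a sentinel; three pass both screening
    rules (ages 60, 70, 80)."""
    df = pd.DataFrame(
        {
            "age": [59, 60, 61, 70, 75, 80],
            "sex": [0, 1, 0, 1, 0, 1],
            "education": [1, 2, "do_not_know", 3, 4, 1],
            "income": [1, 2, 3, 4, 1, 2],
            "bmi": [22.0, 24.0, 23.0, 25.0, 26.0, 21.0],
            "depression": ["no", "no", "yes", "no", "do_not_know", "yes"],
        }
    )
    return df


@pytest.fixture(scope="session")
def recovery_run():
    """One seeded recovery-condition dataset with a 0.1 constant effect."""
    cfg = recovery_config(0.1, seed=5, n=20000)
    return aligned_arrays(cfg)
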