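import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from extarm.pipeline import derive_analysis
from extarm.simulate import SimConfig, generate_study, worked_example_fixture

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_study():
    """One default-configuration synthetic study (seed 7)."""
    return generate_study(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_analysis(default_study):
    """Selection applied to the default study, NSAA change attached."""
    return derive_analysis(default_study)


@pytest.fixture(scope="session")
def fixture_study():
    return worked_example_fixture()


@pytest.fixture()
def tiny_cohort():
    """Hand-built two-arm cohort with known covariates."""
    rng = np.random.default_rng(5)
    n_t, n_e = 10, 40
    arm = ["treated_high"] * n_t + ["external"] * n_e
    return pd.DataFrame({
        "id": [f"P{i}" for i in range(n_t + n_e)],
        "arm": arm,
        "age_screening": rng.uniform(4, 12, n_t + n_e),
        "nsaa_total_baseline": rng.integers(10, 34, n_t + n_e),
        "rise_velocity": rng.uniform(0.15, 0.5, n_t + n_e),
        "run10_velocity": rng.uniform(1.0, 3.5, n_t + n_e),
    })
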