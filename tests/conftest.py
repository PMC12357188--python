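import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import candrift as cd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """The reference scenario at its default size, generated once."""
    config = cd.default_scenario(seed=0)
    panel, truth = cd.generate_cohort(config)
    return config, panel, truth


@pytest.fixture(scope="session")
def default_scored(default_cohort):
    _, panel, truth = default_cohort
    return cd.score_panel(panel, truth)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for structural / interface tests."""
    config = cd.default_scenario(n_patients=3000, seed=11)
    panel, truth = cd.generate_cohort(config)
    return config, panel, truth


@pytest.fixture()
def distinct_probability_panel():
    """100 rows, one year, all-distinct raw probabilities."""
    rng = np.random.default_rng(5)
    probs = rng.permutation(np.linspace(0.01, 0.99, 100))
    return pd.DataFrame(
        {
            "patient_id": np.arange(100),
            "year": 2016,
            "outcome": rng.integers(0, 2, 100),
            "raw_probability": probs,
        }
    )
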