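import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A default-size simulated biopsy cohort with ground truth."""
    from fibromir import synthetic

    params = synthetic.CohortParams(seed=7)
    counts, markers, truth = synthetic.generate_cohort(params)
    return params, counts, markers, truth


@pytest.fixture(scope="session")
def small_design():
    """A default 2x2 FAP/MP x +/-TGFb1 design with ground truth."""
    from fibromir import synthetic

    params = synthetic.DesignParams(seed=11)
    counts, truth = synthetic.generate_design(params)
    return params, counts, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def hand_panel():
    """Three-sample marker panel with hand-computable fibrotic scores."""
    return pd.DataFrame(
        {"COL1A1": [10.0, 5.0, 1.0], "FN1": [20.0, 10.0, 2.0], "ACTA2": [30.0, 15.0, 3.0]},
        index=["S1", "S2", "S3"],
    )
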