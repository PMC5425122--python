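import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from agetrend import (
    ExpressionMatrix,
    SampleMetadata,
    TrendSimConfig,
    generate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the study conditions, shared across tests."""
    return generate_cohort(TrendSimConfig(seed=11))


@pytest.fixture
def tiny_matrix():
    """3 probes x 4 samples with ages spanning both sides of the 50-year cut."""
    values = pd.DataFrame(
        [[5.0, 5.2, 6.0, 6.4], [8.0, 7.9, 7.1, 6.8], [7.0, 7.0, 7.0, 7.0]],
        index=["p_inc", "p_dec", "p_flat"],
        columns=["s1", "s2", "s3", "s4"],
    )
    matrix = ExpressionMatrix(values)
    metadata = SampleMetadata(
        pd.DataFrame(
            {"age": [24.0, 30.0, 50.0, 79.0], "cohort": "discovery"},
            index=pd.Index(["s1", "s2", "s3", "s4"]),
        )
    )
    return matrix, metadata


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
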