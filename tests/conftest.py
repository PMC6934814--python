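import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dietlag import (  # noqa: E402
    FULL_SPAN,
    AnalysisConfig,
    synth_validation_dataset,
)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Stationary-availability dataset with exact linear response, seed 0."""
    series, r, truth = synth_validation_dataset(0, max_lag=5, noise_sd=0.0)
    return series, r, truth


@pytest.fixture(scope="session")
def noiseless_scan(noiseless_dataset):
    """Full-span lag scan of the noiseless dataset at max_lag 5."""
    from dietlag import global_optimize

    series, r, _ = noiseless_dataset
    cfg = AnalysisConfig(max_lag=5, periods=(FULL_SPAN,))
    return global_optimize(series, r, FULL_SPAN, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
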