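import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metaclust import SyntheticConfig, generate_expression, impute_missing

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def blobs():
    """Three well-separated Gaussian blobs, fully observed."""
    return generate_expression(
        SyntheticConfig(n_instances=60, n_features=12, k_true=3, separation=10.0, seed=5)
    )


@pytest.fixture
def noisy_blobs():
    """Moderately separated blobs with missing cells, pre-imputation."""
    return generate_expression(
        SyntheticConfig(
            n_instances=50, n_features=15, k_true=3, separation=5.0,
            missing_rate=0.05, seed=11,
        )
    )


@pytest.fixture
def imputed_blobs(noisy_blobs):
    return impute_missing(noisy_blobs)
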