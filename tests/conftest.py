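import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tensorfe.model import TensorFE
from tensorfe.synthetic import generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_dataset():
    """The default planted synthetic dataset (N=2000, K=300, 30+30 samples)."""
    return generate_dataset()


@pytest.fixture(scope="session")
def td_results(default_dataset):
    """TD fit of the default dataset, shared across tests."""
    ds = default_dataset
    return TensorFE(ds.layer_a, ds.layer_b, ds.annotation).fit()
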