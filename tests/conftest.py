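import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from depograd import KineticModel

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def small_finite_model():
    """Two filaments, 20 monomers, linear gradient: fully enumerable."""
    return KineticModel.from_dimensionless(
        3.0, 5.0, "linear", n_total=20, m_filaments=2, pool_mode="finite"
    )


@pytest.fixture
def ref_linear_model():
    """Large-pool linear-gradient reference parameter set."""
    return KineticModel.from_dimensionless(5.0, 6.66e4, "linear", n_total=2_000_000)


@pytest.fixture
def ref_exponential_model():
    """Large-pool exponential-gradient reference parameter set."""
    return KineticModel.from_dimensionless(200.0, 3.94e4, "exponential", n_total=2_000_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
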