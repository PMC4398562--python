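import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_tensor_pair(rng):
    """Seeded full-rank tensor pair (40 x 4 x 2 and 50 x 4 x 2)."""
    return rng.normal(size=(40, 4, 2)), rng.normal(size=(50, 4, 2))


@pytest.fixture
def planted_cohort():
    """Default synthetic cohort with one tumor-exclusive planted pattern."""
    from tensorgsvd.simulate import SyntheticConfig, generate_pair

    cfg = SyntheticConfig(seed=11)
    d1, d2, truth = generate_pair(cfg)
    return cfg, d1, d2, truth
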