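import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_study():
    """A small two-study simulated dataset shared by scoring/pipeline tests."""
    from stresswm.synthetic_data import SimConfig, generate_study

    config = SimConfig(
        seed=42,
        cells=(
            ("S1", "young", 12),
            ("S1", "older", 10),
            ("S2", "young", 11),
            ("S2", "older", 13),
        ),
    )
    return generate_study(config)
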