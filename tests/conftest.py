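import pytest
from hypothesis import HealthCheck, settings

import silagetea as st

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_params() -> st.ParameterSet:
    """Seeded synthetic parametrization calibrated to the published medians."""
    return st.generate_fixture(st.FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def point_params() -> st.ParameterSet:
    """Fully degenerate (all point-distribution) parametrization."""
    return st.generate_fixture(st.FixtureSpec(seed=1, noise_level=0.0))
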