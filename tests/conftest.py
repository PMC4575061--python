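import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glaucoma_cea import reference_config

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_config():
    """The shipped calibrated reference configuration."""
    return reference_config()


@pytest.fixture(scope="session")
def ref_base_case(ref_config):
    from glaucoma_cea import run_base_case

    return run_base_case(ref_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20150918)
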