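import pytest
from hypothesis import HealthCheck, settings

from bfretest import SyntheticConfig, generate_tests

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mixed_table():
    """A moderate mixed-regime synthetic table shared across tests."""
    cfg = SyntheticConfig(n_tests=300, seed=11, null_prop=0.5)
    tests, truth = generate_tests(cfg)
    return cfg, tests, truth
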