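import pytest
from hypothesis import HealthCheck, settings

from reducer_hta import default_parameter_set

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def base():
    """Packaged base-case parameter set (fresh copy per test)."""
    return default_parameter_set()
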