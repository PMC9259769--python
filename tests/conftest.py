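import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reproduction_report():
    """The one-shot bundled-table reconstruction, computed once per session."""
    from gstpmf.pipeline import reproduce

    return reproduce()


@pytest.fixture(scope="session")
def fixture_records():
    from gstpmf.io import load_fixture

    return load_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
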