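import pytest
from hypothesis import HealthCheck, settings

from fdematel import DEFAULT_SCALE, load_liao_fixture

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scale():
    return DEFAULT_SCALE


@pytest.fixture(scope="session")
def bundle():
    return load_liao_fixture()


@pytest.fixture
def uniform_panel_text():
    """A 3x3 panel file with every off-diagonal cell 'Low influence'."""
    return (
        "criteria,C1,C2,C3\n"
        "C1,-,Low influence,Low influence\n"
        "C2,Low influence,-,Low influence\n"
        "C3,Low influence,Low influence,-\n"
    )
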