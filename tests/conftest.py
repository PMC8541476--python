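import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from soilice.synthetic import make_fixture_suite  # noqa: E402


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The deterministic CSV fixture bundle, written once per session."""
    return make_fixture_suite(tmp_path_factory.mktemp("fixtures"))
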