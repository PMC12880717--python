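import pytest
from hypothesis import HealthCheck, settings

# reproducible property tests: fixed seed behaviour, no flaky deadlines
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 121-patient scanned cohort with known rule behaviour."""
    from fibrotriage import table4_fixture

    return table4_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A small default synthetic cohort shared across tests."""
    from fibrotriage import default_params, generate_cohort

    return generate_cohort(default_params(n=400, seed=42))
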