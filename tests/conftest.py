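import pytest

from hcmkit import load_fixtures
from hcmkit.simulate import generate_cohort


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def records(fixtures):
    return fixtures["records"]


@pytest.fixture(scope="session")
def panel(fixtures):
    return fixtures["panel"]


@pytest.fixture(scope="session")
def controls(fixtures):
    return fixtures["controls"]


@pytest.fixture(scope="session")
def sim_cohort():
    """One deterministic synthetic cohort shared across tests."""
    return generate_cohort(seed=1234)
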