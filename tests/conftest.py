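import pytest

from itpclaims.config import AnalysisConfig
from itpclaims.cohort import select_cohort
from itpclaims.fixture import fixture_small


@pytest.fixture(scope="session")
def tables():
    return fixture_small()


@pytest.fixture()
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def cohort_and_flow(tables):
    return select_cohort(tables, AnalysisConfig())


@pytest.fixture(scope="session")
def cohort(cohort_and_flow):
    return cohort_and_flow[0]
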