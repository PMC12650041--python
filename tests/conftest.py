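import pytest

from faerspv.selection import SelectionCriteria
from faerspv.synthetic import buprenorphine_fig2_fixture, methadone_fig1_fixture
from faerspv.taxonomy import Taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return Taxonomy.default()


@pytest.fixture(scope="session")
def fig1_cohort(taxonomy):
    """190 methadone reports with the published flow-chart category mix."""
    return methadone_fig1_fixture(taxonomy)


@pytest.fixture(scope="session")
def fig2_cohort(taxonomy):
    """79 buprenorphine reports with the published flow-chart category mix."""
    return buprenorphine_fig2_fixture(taxonomy)


@pytest.fixture
def methadone_criteria(taxonomy):
    return SelectionCriteria(
        exposure_substances=frozenset({"methadone"}), taxonomy=taxonomy
    )


@pytest.fixture
def buprenorphine_criteria(taxonomy):
    return SelectionCriteria(
        exposure_substances=frozenset({"buprenorphine"}), taxonomy=taxonomy
    )
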