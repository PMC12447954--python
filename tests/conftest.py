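import pytest
from hypothesis import settings

from paleoneuro import dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table1():
    """The packaged 158-row mammal measurement table."""
    return dataset.load_table("table1_mammals")


@pytest.fixture(scope="session")
def table2():
    """The packaged 8-specimen Bathygenys reevesi within-species table."""
    return dataset.load_table("table2_bathygenys")


@pytest.fixture(scope="session")
def table1_by_label(table1):
    return {r.label: r for r in table1}


@pytest.fixture(scope="session")
def table1_reports(table1):
    return dataset.validate_records(table1)
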