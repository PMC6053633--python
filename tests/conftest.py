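import pytest

from sedqual import aggregate_concentrations, default_constants, default_guidelines
from sedqual import fixtures


@pytest.fixture(scope="session")
def table1_records():
    return fixtures.monthly_concentration_records()


@pytest.fixture(scope="session")
def matrix(table1_records):
    return aggregate_concentrations(table1_records, method="mean")


@pytest.fixture(scope="session")
def guidelines():
    return default_guidelines()


@pytest.fixture(scope="session")
def constants():
    return default_constants()


@pytest.fixture(scope="session")
def reference_eigenvalues():
    return fixtures.reference_pc1_eigenvalues()
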