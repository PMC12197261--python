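import pytest

from ferriqc import TestType, load_ferric_iron_toxicity, species_values
from ferriqc.ssd import points_from_species_values


@pytest.fixture(scope="session")
def fixture_records():
    """The packaged 47-record ferric-iron toxicity table."""
    return load_ferric_iron_toxicity()


@pytest.fixture(scope="session")
def acute_records(fixture_records):
    return [r for r in fixture_records if TestType(r.test_type) is TestType.acute]


@pytest.fixture(scope="session")
def chronic_records(fixture_records):
    return [r for r in fixture_records if TestType(r.test_type) is TestType.chronic]


@pytest.fixture(scope="session")
def acute_species(fixture_records):
    return species_values(fixture_records, TestType.acute)


@pytest.fixture(scope="session")
def chronic_species(fixture_records):
    return species_values(fixture_records, TestType.chronic)


@pytest.fixture(scope="session")
def acute_points(acute_species):
    return points_from_species_values(acute_species)
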