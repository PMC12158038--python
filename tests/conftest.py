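import pytest

from dwarfcall.catalog import default_catalog
from dwarfcall.synthetic_data import fabricate_references

REFERENCE_SEED = 42


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def references(catalog):
    templates, _ = fabricate_references(REFERENCE_SEED, catalog)
    return templates


@pytest.fixture(scope="session")
def placement_report(catalog):
    _, report = fabricate_references(REFERENCE_SEED, catalog)
    return report
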