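import pytest

from oleasrna import data
from oleasrna.io_formats import DEFAULT_ADAPTERS


@pytest.fixture(scope="session")
def known_mirna_rows():
    return data.load_known_mirna_table()


@pytest.fixture(scope="session")
def mature_refs():
    return data.load_mature_reference()


@pytest.fixture(scope="session")
def library_summary():
    return data.load_library_summary()


@pytest.fixture(scope="session")
def size_class_counts():
    return data.load_size_class_counts()


@pytest.fixture(scope="session")
def adapters():
    return DEFAULT_ADAPTERS
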