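import pytest

from sctoforge.dl import snapshot_to_tbox
from sctoforge.fixtures import paper_fixture
from sctoforge.rf2 import taxonomy_index


@pytest.fixture(scope="session")
def snapshot():
    return paper_fixture()


@pytest.fixture(scope="session")
def taxonomy(snapshot):
    return taxonomy_index(snapshot)


@pytest.fixture(scope="session")
def fixture_tbox(snapshot):
    return snapshot_to_tbox(snapshot)
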