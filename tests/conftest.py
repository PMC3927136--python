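import pytest

from pmoaclass.nbc import NBCConfig, train
from pmoaclass.synthetic import mock_reference_db
from pmoaclass.taxonomy import load_packaged_taxonomy


@pytest.fixture(scope="session")
def tree():
    return load_packaged_taxonomy()


@pytest.fixture(scope="session")
def mock_db():
    return mock_reference_db()


@pytest.fixture(scope="session")
def nbc_model(mock_db):
    return train(mock_db, NBCConfig())
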