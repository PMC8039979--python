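import pytest

from cactokey import bundled_key, load_matrix
from cactokey.key_engine import bundled_errata


@pytest.fixture(scope="session")
def matrix():
    return load_matrix()


@pytest.fixture(scope="session")
def key():
    return bundled_key()


@pytest.fixture(scope="session")
def errata():
    return bundled_errata()
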