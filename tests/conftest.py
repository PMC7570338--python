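import pytest

from molcolor.fixtures import NAMED_FIXTURES
from molcolor.perception import ReferenceLibrary


@pytest.fixture(scope="session")
def library() -> ReferenceLibrary:
    return ReferenceLibrary.default()


@pytest.fixture(scope="session")
def fixtures():
    return NAMED_FIXTURES
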