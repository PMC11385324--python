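import pytest

from scrkit.synthdata import make_fixture


@pytest.fixture(scope="session")
def hominini():
    return make_fixture("hominini_like")


@pytest.fixture(scope="session")
def ancestral():
    return make_fixture("ancestral_like")


@pytest.fixture(scope="session")
def mouse():
    return make_fixture("mouse_like")
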