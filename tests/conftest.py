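import pytest

from silentsnp import TranslationParameters, WT_REFERENCE, toy_networks


@pytest.fixture(scope="session")
def params():
    return TranslationParameters()


@pytest.fixture(scope="session")
def wt():
    return WT_REFERENCE


@pytest.fixture(scope="session")
def toys():
    return toy_networks()
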