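import pytest

from omibayes import default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()
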