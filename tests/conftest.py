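import pytest

from housingburden import Registry


@pytest.fixture(scope="session")
def registry() -> Registry:
    return Registry.load()
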