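import pytest

from ionrecipe import builtin_catalog, builtin_registry


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture(scope="session")
def registry(catalog):
    return catalog.registry
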