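import pytest

from cocarbon import CompositionModel, builtin_table1


@pytest.fixture(scope="session")
def model():
    """The published speed limit, 1.16/h."""
    return CompositionModel(1.16)


@pytest.fixture()
def table1():
    return builtin_table1()
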