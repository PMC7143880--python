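import pytest

from bgcrep import load_fixture


@pytest.fixture(scope="session")
def tp_a0598():
    return load_fixture("TP-A0598")


@pytest.fixture(scope="session")
def nbrc3934():
    return load_fixture("NBRC3934")
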