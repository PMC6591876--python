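import pytest

from rectalcea import EconomicSettings, load_fixture


@pytest.fixture(scope="session")
def scrt():
    return load_fixture("table1_scrt")


@pytest.fixture(scope="session")
def lccrt():
    return load_fixture("table1_lccrt")


@pytest.fixture(scope="session")
def settings():
    return EconomicSettings()
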