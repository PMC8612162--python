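import pytest

from ribotraits import allometry, synthetic


@pytest.fixture(scope="session")
def registry():
    return allometry.table1_registry()


@pytest.fixture(scope="session")
def profiles():
    return synthetic.default_profiles()


@pytest.fixture(scope="session")
def steinii(profiles):
    return profiles["Colpoda_steinii"]


@pytest.fixture(scope="session")
def inflata(profiles):
    return profiles["Colpoda_inflata"]
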