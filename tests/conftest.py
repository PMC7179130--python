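import pytest

from cpgroups.predictor import load_table


@pytest.fixture(scope="session")
def liquid_table():
    return load_table("liquid")


@pytest.fixture(scope="session")
def solid_table():
    return load_table("solid")


@pytest.fixture(scope="session")
def fixture_set():
    from cpgroups.fixtures import build_fixture_set
    return build_fixture_set()
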