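import pytest

from foldkin import DEFAULT_CONDITIONS
from foldkin.scenarios import load_scenario_library


@pytest.fixture(scope="session")
def library():
    return load_scenario_library()


@pytest.fixture(scope="session")
def cond():
    return DEFAULT_CONDITIONS


@pytest.fixture(scope="session")
def wt_scheme(library):
    return library["WT"].to_scheme()


@pytest.fixture(scope="session")
def wt_record(library, cond):
    return library["WT"].to_record(cond)
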