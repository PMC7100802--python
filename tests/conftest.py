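import pytest

from despotsim.study_config import (
    BOUND_SET_NAMES,
    SCHEME_NAMES,
    TISSUE_NAMES,
    builtin_bound_set,
    builtin_scheme,
    builtin_tissue,
)


@pytest.fixture(scope="session")
def schemes():
    return {name: builtin_scheme(name) for name in SCHEME_NAMES}


@pytest.fixture(scope="session")
def bound_sets():
    return {name: builtin_bound_set(name) for name in BOUND_SET_NAMES}


@pytest.fixture(scope="session")
def tissues():
    return {name: builtin_tissue(name) for name in TISSUE_NAMES}


@pytest.fixture(scope="session")
def hb():
    return builtin_tissue("HB")


@pytest.fixture(scope="session")
def hb_no_exchange():
    return builtin_tissue("HB", exchange=False)


@pytest.fixture(scope="session")
def s1():
    return builtin_scheme("S1")


@pytest.fixture(scope="session")
def b1():
    return builtin_bound_set("B1")


@pytest.fixture(scope="session")
def wpb():
    return builtin_bound_set("WPB")
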