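import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellsim.document import parse_cellml
from cellsim.fixtures import (IMPORTED_DOC_NAME, MAIN_DOC_NAME,
                              make_conservation, make_decay, make_fhn,
                              make_import_pair, make_invalid_suite, make_nla)
from cellsim.flatten import InMemoryLocator
from cellsim.runtime import build_runtime

settings.register_profile(
    "cellsim", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("cellsim")


@pytest.fixture(scope="session")
def decay_text():
    return make_decay()


@pytest.fixture(scope="session")
def fhn_text():
    return make_fhn()


@pytest.fixture(scope="session")
def nla_text():
    return make_nla()


@pytest.fixture(scope="session")
def valid_texts():
    return {
        "decay": make_decay(),
        "fhn": make_fhn(),
        "nla": make_nla(),
        "conservation": make_conservation(),
    }


@pytest.fixture
def decay_model(decay_text):
    return parse_cellml(decay_text, base_locator="decay.cellml")


@pytest.fixture
def fhn_model(fhn_text):
    return parse_cellml(fhn_text, base_locator="fhn.cellml")


@pytest.fixture
def nla_model(nla_text):
    return parse_cellml(nla_text, base_locator="nla.cellml")


@pytest.fixture(scope="session")
def decay_runtime():
    return build_runtime(parse_cellml(make_decay()))


@pytest.fixture(scope="session")
def fhn_runtime():
    return build_runtime(parse_cellml(make_fhn()))


@pytest.fixture(scope="session")
def nla_runtime():
    return build_runtime(parse_cellml(make_nla()))


@pytest.fixture(scope="session")
def import_pair():
    main, imported = make_import_pair()
    locator = InMemoryLocator({MAIN_DOC_NAME: main,
                               IMPORTED_DOC_NAME: imported},
                              base=MAIN_DOC_NAME)
    return main, imported, locator


@pytest.fixture(scope="session")
def invalid_suite():
    return make_invalid_suite()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
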