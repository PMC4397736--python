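import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from corso.cost_model import augment_model, build_cost_coefficients
from corso.fixtures import (
    make_etc_fixture,
    make_glycolysis_fixture,
    make_loop_fixture,
    make_overflow_fixture,
)


@pytest.fixture(scope="session")
def glycolysis():
    return make_glycolysis_fixture()


@pytest.fixture(scope="session")
def glycolysis_aug(glycolysis):
    model, costs = glycolysis
    coeffs = build_cost_coefficients(model, costs, "combined")
    return augment_model(model, coeffs)


@pytest.fixture(scope="session")
def overflow():
    return make_overflow_fixture()


@pytest.fixture(scope="session")
def overflow_aug(overflow):
    model, costs = overflow
    return augment_model(model, build_cost_coefficients(model, costs, "mw"))


@pytest.fixture(scope="session")
def loop_fixture():
    return make_loop_fixture(seed=0)


@pytest.fixture(scope="session")
def etc_fixture():
    return make_etc_fixture()


@pytest.fixture(scope="session")
def etc_aug(etc_fixture):
    model, costs = etc_fixture
    return augment_model(model, build_cost_coefficients(model, costs, "combined"))
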