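import numpy as np
import pytest

from emoma import (
    LimitationSpec,
    SolverSettings,
    make_fixture,
    solve_fba,
    solve_pfba,
)


@pytest.fixture
def settings():
    return SolverSettings()


@pytest.fixture
def toy_a():
    return make_fixture("TOY-A")


@pytest.fixture
def toy_b():
    return make_fixture("TOY-B")


@pytest.fixture
def toy_c():
    return make_fixture("TOY-C")


@pytest.fixture(scope="session")
def toy_y():
    return make_fixture("TOY-Y")


@pytest.fixture
def nitrogen_block():
    return LimitationSpec("EX_nh4")


@pytest.fixture
def toy_b_reference(toy_b, settings):
    fba = solve_fba(toy_b, settings)
    return solve_pfba(toy_b, fba.f_opt, settings)


@pytest.fixture(scope="session")
def toy_y_reference(toy_y):
    settings = SolverSettings()
    fba = solve_fba(toy_y, settings)
    return solve_pfba(toy_y, fba.f_opt, settings)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
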