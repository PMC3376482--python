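import warnings

import pytest

from lungflow import (make_fixture, run_cycle, solve_expiration,
                      solve_inspiration)


@pytest.fixture(scope="session")
def paper2():
    """Two-compartment reference fixture (printed parameter set)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_fixture("paper_2comp")


@pytest.fixture(scope="session")
def paper4():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_fixture("paper_4comp")


@pytest.fixture(scope="session")
def insp2(paper2):
    model, spec = paper2
    return solve_inspiration(model, spec)


@pytest.fixture(scope="session")
def bvp2(paper2):
    model, spec = paper2
    return solve_expiration(model, spec)


@pytest.fixture(scope="session")
def cycle2(paper2):
    model, spec = paper2
    return run_cycle(model, spec)
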