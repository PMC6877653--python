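import pytest

from epiconserve import load_fixture
from epiconserve.synthetic_data import (
    SimulationParams,
    simulate_family,
    tile_epitopes,
)


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1_tm")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_ak")


@pytest.fixture(scope="session")
def small_params():
    """A reduced family: same structure as the defaults, faster to scan."""
    return SimulationParams(
        ancestor_length=90,
        conserved_blocks=((1, 20), (71, 90)),
        group_sizes={"crustacean": 4, "cockroach": 3, "mite": 3, "mollusc": 6},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_family(small_params):
    return simulate_family(small_params)


@pytest.fixture(scope="session")
def small_epitopes(small_family):
    return tile_epitopes(small_family.ancestor, (15,), 5)
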