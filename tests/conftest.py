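import numpy as np
import pytest

import fullcycle.synthetic_landscape as sl


@pytest.fixture(scope="session")
def grid10():
    return sl.make_planning_grid(10, 10, 8.4, origin=(30.0, -100.0))


@pytest.fixture(scope="session")
def small_cube(grid10):
    pool = sl.default_species_pool(grid10, 3, seed=11)
    return sl.build_cube(pool, grid10)


@pytest.fixture(scope="session")
def species_pool(grid10):
    return sl.default_species_pool(grid10, 3, seed=11)
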