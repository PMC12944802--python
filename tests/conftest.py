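import numpy as np
import pytest

import chdspatial as cs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grid3():
    return cs.make_lattice(3, 3)


@pytest.fixture(scope="session")
def grid3_rook(grid3):
    return cs.build_weights(grid3, rule="rook")


@pytest.fixture(scope="session")
def torus_lattice():
    return cs.make_lattice(6, 5, torus=True)


@pytest.fixture(scope="session")
def torus_weights(torus_lattice):
    return cs.build_weights(torus_lattice, rule="queen")


def random_weights_case(rng, max_side=6):
    """A random small lattice weights matrix plus random x, y vectors."""
    nx = int(rng.integers(2, max_side + 1))
    ny = int(rng.integers(2, max_side + 1))
    torus = bool(rng.integers(2))
    rule = "queen" if rng.integers(2) else "rook"
    areas = cs.make_lattice(nx, ny, torus=torus)
    W = cs.build_weights(areas, rule=rule)
    n = nx * ny
    x = rng.normal(size=n) * rng.uniform(0.5, 20) + rng.uniform(-50, 50)
    y = rng.normal(size=n) * rng.uniform(0.5, 20) + rng.uniform(-50, 50)
    return W, x, y
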