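import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import circuitpareto as cp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# -- shared, expensive grids (computed once per session) --------------------

@pytest.fixture(scope="session")
def pos_autoreg_table():
    """Sensitivities of positive autoregulation on the default 100x100 grid."""
    m = cp.make_circuit("positive_autoreg")
    return m, cp.default_grid(m), cp.grid_sensitivities(
        m, cp.default_grid(m))


@pytest.fixture(scope="session")
def neg_autoreg_table():
    """Negative autoregulation on the default 100x100 grid with the
    feedback strength 2 inserted as a grid value."""
    m = cp.make_circuit("negative_autoreg")
    grid = cp.default_grid(m, extra={"alpha": [2.0]})
    return m, grid, cp.grid_sensitivities(m, grid)


def _census(name, resolution):
    m = cp.make_circuit(name)
    grid = cp.default_grid(m, resolution)
    return cp.tradeoff_census(m, grid)


@pytest.fixture(scope="session")
def census_30():
    """30^3 trade-off censuses of the three standard two-species circuits."""
    return {name: _census(name, 30)
            for name in ("positive_negative", "double_positive", "toggle")}


@pytest.fixture(scope="session")
def census_15():
    """Half-resolution censuses for the grid-refinement stability check."""
    return {name: _census(name, 15)
            for name in ("positive_negative", "double_positive", "toggle")}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


def random_theta(model, rng, leak_max=10.0):
    """An in-range random parameter point for a circuit."""
    theta = {}
    for p in model.params:
        if p == "n":
            theta[p] = float(rng.uniform(*cp.circuits.COOPERATIVITY_RANGE))
        elif p == "gamma":
            theta[p] = 1.0
        elif p == "L":
            theta[p] = float(rng.uniform(0.0, leak_max))
        else:
            theta[p] = float(rng.uniform(*cp.circuits.STRENGTH_RANGE))
    return theta
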