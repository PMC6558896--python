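import numpy as np
import pytest

from aerodose.size_distribution import NumberSizeDistribution, SizeGrid
from aerodose.synthetic import airfield_cycle_scenario, generate_timeseries


@pytest.fixture(scope="session")
def default_grid():
    return SizeGrid.default()


@pytest.fixture(scope="session")
def airfield_series():
    """Two-cycle jet-shelter scenario sampled at 10 s, noiseless truth."""
    return generate_timeseries(airfield_cycle_scenario(), step=10.0, seed=42)


@pytest.fixture
def monodisperse_dist():
    """Single-bin distribution: 1e4 cm^-3 at exactly 100 nm midpoint."""
    # edges chosen so the geometric midpoint is exactly 1e-7 m
    grid = SizeGrid([9e-8, 1e-14 / 9e-8])
    return NumberSizeDistribution(grid, [1e4])
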