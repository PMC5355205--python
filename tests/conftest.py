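import numpy as np
import pytest

import tallgrass as tg
from tallgrass.forage import truth_raster_stack
from tallgrass.landscape import generate_burn_history, generate_weather


@pytest.fixture(scope="session")
def small_landscape():
    """60×60-cell landscape (600 m square) with burns and one-year weather."""
    terrain = tg.generate_terrain(60, 60, seed=7)
    burns = generate_burn_history(terrain.shape, [1, 2, 4, 20], [2011, 2012], seed=7)
    weather = generate_weather([2011, 2012], drought_years=[2012], seed=7)
    return terrain, burns, weather


@pytest.fixture(scope="session")
def small_stack(small_landscape):
    """Truth-surface biweekly covariate stack for the 2011 season."""
    terrain, burns, weather = small_landscape
    return truth_raster_stack(terrain, weather, burns, 2011)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
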