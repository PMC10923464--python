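import numpy as np
import pytest

from sodamap import CellMask, RingSpec, SimScenario, simulate_patterns


@pytest.fixture(scope="session")
def rectangle_mask() -> CellMask:
    """10 x 10 um rectangle window at 100 nm pixels (2 px background border)."""
    grid = np.zeros((100, 100), dtype=bool)
    grid[2:-2, 2:-2] = True
    return CellMask(grid, pixel_size=100.0)


@pytest.fixture(scope="session")
def default_rings() -> RingSpec:
    return RingSpec.uniform(30.0, 10)


@pytest.fixture(scope="session")
def coupled_scenario():
    """Baseline coupled condition: q=0.5 at 50 +/- 10 nm, 300 spots/channel."""
    sc = SimScenario(seed=7)
    mask, s1, s2, truth = simulate_patterns(sc)
    return sc, mask, s1, s2, truth
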