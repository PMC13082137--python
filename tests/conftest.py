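import numpy as np
import pytest

from clotsim2d.geometry import Grid2D, PlateletPlug, PlugConfig, rasterize
from clotsim2d.params import default_parameters


@pytest.fixture
def kin():
    return default_parameters().kinetics


@pytest.fixture
def fluid():
    return default_parameters().fluid


def empty_mask(length=10.0, height=10.0, h=1.0, se_strip=None):
    """An all-fluid channel mask (no platelets)."""
    grid = Grid2D(length=length, height=height, h=h)
    plug = PlateletPlug(np.empty((0, 2)), 1.23, PlugConfig())
    return rasterize(plug, grid, se_strip or (length, length))


@pytest.fixture
def small_empty_mask():
    return empty_mask(20.0, 10.0, 0.5)
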