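import numpy as np
import pytest

from alevbm import coords, synthetic_data
from alevbm.foci_prep import MaskVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20130509)


@pytest.fixture
def grid16():
    """16^3 grid, 2-mm isotropic, centered on the world origin."""
    return coords.isotropic_grid((16, 16, 16), 2.0)


@pytest.fixture
def corner_grid():
    """2-mm isotropic grid whose voxel (0,0,0) center sits at the world origin."""
    return coords.isotropic_grid((10, 10, 10), 2.0, origin=(0.0, 0.0, 0.0))


@pytest.fixture
def single_voxel_mask(corner_grid):
    """One foreground voxel whose center is the world origin."""
    vox = np.zeros(corner_grid.shape, dtype=bool)
    vox[0, 0, 0] = True
    return MaskVolume(grid=corner_grid, voxels=vox)


@pytest.fixture
def toy_mask(grid16):
    return synthetic_data.make_toy_mask(grid16, semi_axes_mm=(10.0, 8.0, 7.0))
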