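"""Shared fixtures: small, fast phantom configurations for unit tests.

The head geometry is fixed in millimetres, so coarse test grids raise the
voxel spacing to keep the whole phantom inside the field of view.
"""

import numpy as np
import pytest

from adslice.phantom import PhantomSpec


@pytest.fixture(scope="session")
def default_spec():
    """Desk-scale spec: 96 voxels at 2 mm."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def coarse_spec():
    """Very coarse spec (32 voxels at 6 mm) for generator-law tests."""
    return PhantomSpec(grid_size=32, voxel_spacing_mm=6.0)


@pytest.fixture(scope="session")
def small_spec():
    """Intermediate spec (48 voxels at 4 mm) for fast end-to-end smokes."""
    return PhantomSpec(grid_size=48, voxel_spacing_mm=4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
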