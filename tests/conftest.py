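import numpy as np
import pytest

from doseatlas.volume_io import GridSpec
from doseatlas.synthetic_cohort import (
    PhantomParams,
    make_atlas_phantom,
    make_template_phantom,
)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """24^3 grid at 6 mm: the fast grid for statistical tests."""
    return GridSpec.centered(24, 6.0)


@pytest.fixture(scope="session")
def reg_grid() -> GridSpec:
    """64^3 grid at 3 mm: the registration benchmark grid."""
    return GridSpec.centered(64, 3.0)


@pytest.fixture(scope="session")
def phantom(small_grid):
    """(template, truth) pair on the small grid, default parameters."""
    return make_template_phantom(small_grid, seed=1)


@pytest.fixture(scope="session")
def atlas(small_grid):
    return make_atlas_phantom(small_grid)


@pytest.fixture(scope="session")
def noiseless_params() -> PhantomParams:
    return PhantomParams(noise_sigma_gy=0.0, effect_size_gy=0.0, hu_noise=0.0)
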