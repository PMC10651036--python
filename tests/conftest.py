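import numpy as np
import pytest

from grayscape import FixtureRecipe, GrayLevelRaster, generate


@pytest.fixture
def demo_4x4():
    """A 4x4 nominal map with no missing pixels (16 pixels, 24 adjacencies)."""
    return GrayLevelRaster(np.array([
        [1, 1, 2, 2],
        [1, 3, 3, 2],
        [1, 3, 3, 2],
        [2, 2, 2, 2],
    ]))


@pytest.fixture
def constant_40():
    return GrayLevelRaster(np.full((9, 9), 40, dtype=np.uint8))


def random_fixture(seed, shape=(15, 15), levels=(0, 1, 2, 3, 40, 90), missing=0.1):
    """A seeded random categorical raster with missing holes."""
    return generate(
        FixtureRecipe("random-categorical", shape, levels, missing_frac=missing, seed=seed)
    )
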