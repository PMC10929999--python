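import numpy as np
import pytest

from selfseg import (
    CorruptionConfig,
    PhantomConfig,
    generate_phantom,
)

#: compact grid used throughout the unit tests — fast but anisotropic,
#: with every organ present
TEST_GRID = (16, 64, 64)
TEST_SPACING = (6.5, 2.656, 2.656)


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(grid_shape=TEST_GRID, spacing_mm=TEST_SPACING, seed=7)


@pytest.fixture(scope="session")
def phantom_case(phantom_config):
    """One generated (volume, labels) pair, shared read-only."""
    return generate_phantom(phantom_config, "case_000")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, shape=(8, 8, 8), p=0.4):
    return rng.random(shape) < p
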