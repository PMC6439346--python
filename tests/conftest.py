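import numpy as np
import pytest

from neuroscene import (
    make_icosphere,
    make_synthetic_atlas,
    make_synthetic_brain,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def icosphere10():
    """Icosphere of radius 10 mm centered at the origin (2562 vertices)."""
    return make_icosphere(subdiv=4, radius=10.0)


@pytest.fixture(scope="session")
def brain():
    """Two-lobe synthetic brain fixture, ~5k faces."""
    return make_synthetic_brain(subdiv=3, gap=2.0, seed=7)


@pytest.fixture(scope="session")
def small_brain():
    return make_synthetic_brain(subdiv=2, gap=2.0, seed=7)


@pytest.fixture(scope="session")
def atlas():
    return make_synthetic_atlas(n_rois=4, shape=(40, 48, 40), seed=3)
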