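import numpy as np
import pytest

from rfkit.fixtures import bandlimited_noise
from rfkit.spatial import SpatialCovariance


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def iso_cov():
    return SpatialCovariance.from_scale(1.0)


@pytest.fixture
def noise64():
    return bandlimited_noise((64, 64), cutoff=0.15, seed=42)
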