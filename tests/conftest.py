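import numpy as np
import pytest

from larvapose.annotations import KeypointSet
from larvapose.synthetic import LarvaShapeParams, generate_larva


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_keypoints(rng):
    """A valid 26-point set scattered over a 96x72 canvas."""
    xy = np.column_stack([rng.uniform(4, 92, 26), rng.uniform(4, 68, 26)])
    return KeypointSet.from_array(xy)


@pytest.fixture(scope="session")
def canonical_larva():
    """Identity-pose synthetic larva on the default small canvas."""
    return generate_larva(LarvaShapeParams(seed=3), (96, 72))
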