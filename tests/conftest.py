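import numpy as np
import pytest

from ethopose.io import BodyPartSet, PoseTrack
from ethopose.simulate import DEFAULT_TEMPLATE


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def parts():
    return BodyPartSet(tuple(DEFAULT_TEMPLATE))


@pytest.fixture
def random_track(rng, parts):
    """A finite random 10-part track (no anatomical structure)."""
    n = 50
    coords = rng.uniform(0, 1000, size=(n, len(parts), 2))
    likelihood = rng.uniform(0.5, 1.0, size=(n, len(parts)))
    return PoseTrack(parts, coords, likelihood, fps=119.88)


def make_track(coords, parts, likelihood=None, fps=None):
    coords = np.asarray(coords, dtype=float)
    if likelihood is None:
        likelihood = np.ones(coords.shape[:2])
    return PoseTrack(parts, coords, likelihood, fps)
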