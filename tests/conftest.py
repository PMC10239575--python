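import numpy as np
import pytest

from nucgraph import CentroidSet, EdgeFeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(20230603)


@pytest.fixture
def square_with_interior():
    """Four points: triangle hull plus one interior point (2D)."""
    return CentroidSet((0, 1, 2, 3), [(0.0, 0.0), (2.0, 0.0), (1.0, 2.0), (1.0, 0.5)])


@pytest.fixture
def toy_features():
    """The minimal three-edge feature table used in the threshold examples."""
    return EdgeFeatureTable(
        i=[0, 1, 2], j=[1, 2, 3], r=[1.0, 2.0, 3.0], theta=[10.0, 20.0, 30.0]
    )


def random_general_position(rng, n, dim):
    """Random points, rejection-sampled away from near-degeneracy."""
    while True:
        pts = rng.uniform(0, 10, size=(n, dim))
        from scipy.spatial.distance import pdist

        if pdist(pts).min() > 1e-3:
            return pts


def random_similarity(rng, dim, allow_reflection=True):
    """Random (rotation [+ reflection], uniform scale, translation)."""
    q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
    if not allow_reflection and np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    scale = float(rng.uniform(0.2, 5.0))
    offset = rng.uniform(-50, 50, size=dim)
    return q, scale, offset
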