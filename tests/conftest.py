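import numpy as np
import pytest

from axonfield.io import SkeletonNode, SkeletonTree


def make_chain(points, tree_id=1):
    """SkeletonTree from an ordered list of (x, y, z) positions."""
    nodes = [
        SkeletonNode(i + 1, 2, np.asarray(p, dtype=float), 1.0, i if i > 0 else -1)
        for i, p in enumerate(points)
    ]
    return SkeletonTree(nodes=nodes, tree_id=tree_id)


@pytest.fixture
def straight_tree():
    """Unit-spaced straight skeleton along x at y=z=8 (already resampled)."""
    return make_chain([(float(i), 8.0, 8.0) for i in range(16)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
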