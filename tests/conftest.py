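import numpy as np
import pytest

from multimod import MultiNetwork


def make_mn(layers, labels=None, weighted=None):
    """Build a MultiNetwork from dense arrays, auto-detecting weightedness."""
    layers = [np.asarray(w, dtype=float) for w in layers]
    n = layers[0].shape[0]
    if labels is None:
        labels = [f"n{i}" for i in range(n)]
    if weighted is None:
        weighted = any(np.any((w != 0) & (w != 1)) for w in layers)
    return MultiNetwork(labels, layers, [f"layer_{t}" for t in range(len(layers))], weighted)


def symmetric_random(rng, n, zero_diag=True):
    a = rng.random((n, n))
    s = np.triu(a, 1) + np.triu(a, 1).T
    return s


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_layer_shared_edge():
    """Two unweighted layers over 4 nodes: edge (0,1) in both layers,
    edge (2,3) only in layer 0."""
    w1 = np.zeros((4, 4))
    w1[0, 1] = w1[1, 0] = 1
    w1[2, 3] = w1[3, 2] = 1
    w2 = np.zeros((4, 4))
    w2[0, 1] = w2[1, 0] = 1
    return make_mn([w1, w2])
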