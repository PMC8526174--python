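import numpy as np
import pytest

from netdyn import graphs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def modular_graph():
    """The 60-node, 420-edge modular substrate (4 cliques of 15, p=0.23)."""
    return graphs.make_modular(4, 15, 0.23, seed=1)


@pytest.fixture(scope="session")
def randomized_modular_graph(modular_graph):
    """Fully randomized counterpart (500 degree-preserving swaps)."""
    return graphs.randomize_degree_preserving(modular_graph, 500, seed=2)


def assert_simple_adjacency(A):
    A = np.asarray(A)
    assert A.ndim == 2 and A.shape[0] == A.shape[1]
    assert np.isin(A, (0, 1)).all()
    assert (np.diag(A) == 0).all()
    assert np.array_equal(A, A.T)
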