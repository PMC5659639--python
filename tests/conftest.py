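import numpy as np
import pytest

from sfhopfield import NetworkSpec, WeightedGraph, sample_graph, sample_patterns


@pytest.fixture(scope="session")
def er_weights():
    from sfhopfield import weights_for
    return weights_for("er", 1000, 5.0)


@pytest.fixture(scope="session")
def nine_node_graph():
    """Small sparse fixture in the style of the toy retrieval example:
    9 nodes, 8 edges (mean degree 16/9)."""
    edges = np.array([[0, 1], [0, 2], [1, 3], [2, 4], [3, 5], [4, 6], [5, 7], [6, 8]])
    spec = NetworkSpec("er", 9, K=16 / 9)
    deg = np.zeros(9, dtype=int)
    np.add.at(deg, edges[:, 0], 1)
    np.add.at(deg, edges[:, 1], 1)
    return WeightedGraph(spec=spec, w=np.full(9, 1 / 9), edges=edges, degrees=deg)


@pytest.fixture(scope="session")
def er_graph_300():
    return sample_graph(NetworkSpec("er", 300, K=5.0), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
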