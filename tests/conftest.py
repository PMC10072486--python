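import numpy as np
import networkx as nx
import pytest

from coalnet.graph import UndirectedGraph, load_fixture
from coalnet.null_model import exact_corrected_weights
from coalnet.weights import raw_weights


@pytest.fixture(scope="session")
def path3():
    return load_fixture("path3")


@pytest.fixture(scope="session")
def triangle():
    return load_fixture("triangle")


@pytest.fixture(scope="session")
def two_triangles():
    return load_fixture("two_triangles")


@pytest.fixture(scope="session")
def zachary():
    return load_fixture("zachary")


@pytest.fixture(scope="session")
def path3_wstar(path3):
    return exact_corrected_weights(path3)


@pytest.fixture(scope="session")
def zachary_wstar(zachary):
    return exact_corrected_weights(zachary)


def random_graph(n: int, p_edge: float, seed: int, min_degree: int = 1) -> UndirectedGraph:
    """Random simple graph with all degrees >= min_degree (patched by adding
    edges from a cycle), for property sweeps."""
    rng = np.random.default_rng(seed)
    gnx = nx.gnp_random_graph(n, p_edge, seed=int(rng.integers(0, 2**31)))
    order = list(range(n))
    for i in order:
        while gnx.degree(i) < min_degree:
            j = int(rng.integers(0, n))
            if j != i and not gnx.has_edge(i, j):
                gnx.add_edge(i, j)
    return UndirectedGraph.from_edge_pairs(list(gnx.edges()), nodes=order)


@pytest.fixture(scope="session")
def small_weighted_suite():
    """Random small graphs with raw and exact-corrected weight tables."""
    suite = []
    for seed in range(8):
        g = random_graph(6 + seed % 3, 0.5, seed=seed)
        suite.append((g, raw_weights(g), exact_corrected_weights(g)))
    return suite
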