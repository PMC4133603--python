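import itertools

import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def bridge_of_triangles() -> nx.Graph:
    """Two triangles a-b-c and d-e-f joined by the bridge c-d."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("d", "e"), ("e", "f"), ("d", "f"),
                      ("c", "d")])
    return g


def random_graph(rng: np.random.Generator, n_max: int = 8) -> nx.Graph:
    """Small Erdos-Renyi-style random graph for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.2, 0.9))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u, v in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(u, v)
    return g
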