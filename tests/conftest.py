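import numpy as np
import pytest

from netpharm.graph_io import SignedDiGraph


def random_signed_graph(rng: np.random.Generator, n: int, p_edge: float = 0.15,
                        p_neg: float = 0.3) -> SignedDiGraph:
    """Erdos-Renyi style random signed digraph (no self-loops)."""
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p_edge:
                sign = -1 if rng.random() < p_neg else 1
                edges.append((f"v{i}", f"v{j}", sign))
    return SignedDiGraph.from_edges(edges, nodes=[f"v{i}" for i in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_signed_graph():
    """Strongly connected 5-node signed graph (no dangling nodes)."""
    return SignedDiGraph.from_edges(
        [
            ("A", "B", 1),
            ("B", "C", -1),
            ("C", "A", 1),
            ("C", "D", -1),
            ("D", "E", 1),
            ("E", "A", -1),
            ("B", "D", 1),
        ]
    )
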