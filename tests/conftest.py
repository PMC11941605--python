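import numpy as np
import pytest

from ldembed.graph_core import Digraph, canonical_order, toy_digraph, toy_labels

# Adjacency of the line digraph of the six-node example, frozen from the
# hand derivation: row e_i has a 1 at e_j iff head(e_i) = tail(e_j), with
# edges e1=(a,b) … e9=(f,e) in lexicographic order.
TOY_LINE_ADJACENCY = np.array(
    [
        [0, 1, 1, 0, 0, 0, 0, 0, 0],
        [1, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 1, 1, 0, 0, 0, 0],
        [1, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 1, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 1, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 1, 1],
        [0, 0, 0, 0, 0, 1, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 1, 0, 0],
    ],
    dtype=np.int64,
)


@pytest.fixture
def toy():
    return toy_digraph()


@pytest.fixture
def toy_two_communities():
    return toy_labels()


def random_digraph(seed: int, n_max: int = 10, p: float = 0.3) -> Digraph:
    """Seeded Erdős–Rényi-style digraph (may contain sinks/sources)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, n_max + 1))
    nodes = tuple(f"n{i:02d}" for i in range(n))
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    if not edges:
        edges = [(nodes[0], nodes[1])]
    used = tuple(sorted({x for e in edges for x in e}))
    return canonical_order(Digraph(used, tuple(edges)))
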