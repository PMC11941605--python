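"""Hub/authority-preserving edge sampling for digraph sparsification.

Computing ℓG is quadratic in the worst case, so large digraphs are thinned
before the line digraph is built.  Each edge e = (i, j) is kept with
probability proportional to

    p_e = (1/2n)·(1/dout(i) + 1/din(j)),

which protects edges whose endpoints have few alternatives: an edge out of
a low-out-degree tail, or into a low-in-degree head, is nearly irreplaceable
for preserving in/out-degree structure (and hence the symmetrized spectrum),
while edges between well-connected hubs and authorities are redundant.  On
a graph without sinks or sources the p_e sum to exactly 1.

The sample size guaranteeing spectral error below ε with probability p is
k ≥ 128·(2n/ε²)·ln(2n/p); experiments are instead parameterized by the
inverse degree of sparsification z ∈ (0, 1], the fraction of edges kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph_core import Digraph

__all__ = [
    "SparsifierPlan",
    "edge_sampling_probabilities",
    "sample_size_bound",
    "sparsify",
]


@dataclass(frozen=True)
class SparsifierPlan:
    """Per-edge sampling probabilities plus the (ε, p) → k spectral bound."""

    edges: tuple[tuple[str, str], ...]
    probabilities: np.ndarray
    epsilon: float | None = None
    failure_probability: float | None = None
    k: int | None = None


def edge_sampling_probabilities(
    G: Digraph,
    epsilon: float | None = None,
    failure_probability: float | None = None,
) -> SparsifierPlan:
    """p_e = (1/2n)·(1/dout(i) + 1/din(j)) for every edge e = (i, j)."""
    if G.m == 0:
        raise ValueError("graph has no edges")
    dout = G.out_degrees()
    din = G.in_degrees()
    idx = G.node_index
    p = np.array(
        [
            (1.0 / dout[idx[u]] + 1.0 / din[idx[v]]) / (2.0 * G.n)
            for u, v in G.edges
        ]
    )
    k = None
    if epsilon is not None and failure_probability is not None:
        k = sample_size_bound(G.n, epsilon, failure_probability)
    return SparsifierPlan(
        edges=G.edges,
        probabilities=p,
        epsilon=epsilon,
        failure_probability=failure_probability,
        k=k,
    )


def sample_size_bound(n: int, epsilon: float, p: float) -> int:
    """k = ceil(128·(2n/ε²)·ln(2n/p)), the spectral-approximation sample size."""
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    return math.ceil(128.0 * (2.0 * n / epsilon**2) * math.log(2.0 * n / p))


def sparsify(G: Digraph, z: float, seed: int) -> Digraph:
    """Keep round(z·m) distinct edges, drawn with weights ∝ p_e (seeded).

    Sampling is without replacement via exponential keys (weighted
    reservoir); surviving edges keep their original weights and are not
    reweighted, and the node set is unchanged (isolated nodes are retained
    so embeddings stay index-aligned across a sweep).  z = 1 returns G
    itself.
    """
    if not 0 < z <= 1:
        raise ValueError("z must lie in (0, 1]")
    if z == 1.0:
        return G
    k = round(z * G.m)
    if k < 1:
        raise ValueError(f"z = {z} keeps no edges (round(z·m) = {k})")
    plan = edge_sampling_probabilities(G)
    rng = np.random.default_rng(seed)
    keys = rng.exponential(size=G.m) / plan.probabilities
    keep = np.sort(np.argpartition(keys, k - 1)[:k])
    edges = tuple(G.edges[i] for i in keep)
    weights = None
    if G.weights is not None:
        weights = tuple(G.weights[i] for i in keep)
    return Digraph(G.nodes, edges, weights, G.labels)
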