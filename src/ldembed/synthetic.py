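"""Seeded synthetic digraph generators for testing every pipeline stage.

Two families:

* :func:`directed_sbm` — a directed stochastic block model with assortative
  communities, the structure under which edge labels inherited from
  destination nodes are a faithful proxy for community membership.  Each
  ordered pair (i, j), i ≠ j, receives an edge independently with the
  intra- or inter-block probability.  Optionally, sinks and sources are
  repaired by adding edges along a random block-respecting Hamiltonian
  cycle so that walk-based operators are well defined everywhere.
* :func:`strongly_connected_random` — a random Hamiltonian directed cycle
  plus extra random edges; strongly connected by construction, the regime
  in which rank(A_ℓG) = n is guaranteed.

Both are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import Digraph, NodeLabeling, canonical_order

__all__ = ["SBMSpec", "SBMSample", "directed_sbm", "strongly_connected_random"]


@dataclass(frozen=True)
class SBMSpec:
    """Directed stochastic-block-model parameters.

    Defaults are the two-community assortative regime used throughout the
    tests: blocks of 20 nodes, intra-block edge probability 0.3, inter-block
    probability 0.02, sinks and sources repaired.
    """

    block_sizes: tuple[int, ...] = (20, 20)
    p_in: float = 0.3
    p_out: float = 0.02
    forbid_sinks_sources: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.block_sizes):
            raise ValueError("block sizes must be ≥ 2")
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 ≤ p_out < p_in ≤ 1")


@dataclass(frozen=True)
class SBMSample:
    """A generated SBM digraph with its block labeling and repair count."""

    graph: Digraph
    labels: NodeLabeling
    repair_edge_count: int

    def __iter__(self):
        # allow `graph, labels = directed_sbm(spec)` unpacking
        return iter((self.graph, self.labels))


def directed_sbm(spec: SBMSpec) -> SBMSample:
    """Sample a directed SBM; labels are block ids ('B0', 'B1', …)."""
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.block_sizes)
    width = max(3, len(str(n - 1)))
    nodes = tuple(f"v{i:0{width}d}" for i in range(n))
    block_of = np.empty(n, dtype=np.int64)
    start = 0
    for b, size in enumerate(spec.block_sizes):
        block_of[start : start + size] = b
        start += size
    prob = np.where(block_of[:, None] == block_of[None, :], spec.p_in, spec.p_out)
    np.fill_diagonal(prob, 0.0)
    draw = rng.random((n, n)) < prob
    edge_set = {(nodes[i], nodes[j]) for i, j in zip(*np.nonzero(draw))}

    repairs = 0
    if spec.forbid_sinks_sources:
        # random Hamiltonian cycle visiting blocks contiguously; each repair
        # edge u→succ(u) fixes sink u and source succ(u) without creating
        # new ones
        order: list[int] = []
        start = 0
        for size in spec.block_sizes:
            blk = list(range(start, start + size))
            rng.shuffle(blk)
            order.extend(blk)
            start += size
        succ = {order[i]: order[(i + 1) % n] for i in range(n)}
        dout = np.zeros(n, dtype=np.int64)
        din = np.zeros(n, dtype=np.int64)
        idx = {u: i for i, u in enumerate(nodes)}
        for u, v in edge_set:
            dout[idx[u]] += 1
            din[idx[v]] += 1
        changed = True
        while changed and ((dout == 0).any() or (din == 0).any()):
            changed = False
            for i in range(n):
                j = succ[i]
                if (dout[i] == 0 or din[j] == 0) and (nodes[i], nodes[j]) not in edge_set:
                    edge_set.add((nodes[i], nodes[j]))
                    dout[i] += 1
                    din[j] += 1
                    repairs += 1
                    changed = True

    labels = NodeLabeling.from_single(
        {nodes[i]: f"B{block_of[i]}" for i in range(n)}
    )
    graph = canonical_order(Digraph(nodes, tuple(sorted(edge_set)))).with_labels(labels)
    return SBMSample(graph=graph, labels=labels, repair_edge_count=repairs)


def strongly_connected_random(n: int, extra_edges: int, seed: int) -> Digraph:
    """Random Hamiltonian directed cycle plus ``extra_edges`` distinct arcs."""
    if n < 2:
        raise ValueError("n must be ≥ 2")
    max_extra = n * (n - 1) - n
    if extra_edges > max_extra:
        raise ValueError(f"extra_edges must be ≤ {max_extra} for n = {n}")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n - 1)))
    nodes = tuple(f"v{i:0{width}d}" for i in range(n))
    perm = rng.permutation(n)
    edge_set = {
        (nodes[perm[i]], nodes[perm[(i + 1) % n]]) for i in range(n)
    }
    candidates = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(n)
        if i != j and (nodes[i], nodes[j]) not in edge_set
    ]
    picks = rng.choice(len(candidates), size=extra_edges, replace=False)
    for k in picks:
        edge_set.add(candidates[k])
    return canonical_order(Digraph(nodes, tuple(sorted(edge_set))))
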