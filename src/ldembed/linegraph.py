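"""Line digraphs, incidence matrices, the class factorization, and exact rank.

The line digraph ℓG of a digraph G has one node per directed edge of G, and
an arc e → f whenever the head of e equals the tail of f.  Writing H and T
for the n×m head/tail incidence matrices (H[i, j] = 1 iff node i is the
target of edge j; T[i, j] = 1 iff node i is its source),

    A_G = T·Hᵀ          A_ℓG = Hᵀ·T.

Any two rows of A_ℓG are either identical or have disjoint support: edges
ending at the same node link onwards identically.  Grouping edges by their
destination node therefore factorizes A_ℓG = Ein·Eout with Ein an m×n
indicator (Ein = Hᵀ) and Eout the n×m matrix of distinct rows (Eout = T),
and Eout·Ein recovers A_G up to the permutation Q relating class order to
node order.  For strongly connected G this gives rank(A_ℓG) = n — the rank
property that makes line-digraph embeddings retain ≈ n informative
directions no matter how large m is.

Iterated line digraphs ℓᵖG are p-fold applications of the operator; their
nodes correspond to directed length-p paths of G and are named by joining
the path with ``>`` (``a>b>c``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import sympy

from .graph_core import Digraph, NodeLabeling

__all__ = [
    "IncidencePair",
    "LineDigraph",
    "ClassFactorization",
    "incidence_matrices",
    "line_digraph",
    "iterate_line_digraph",
    "inherit_labels",
    "class_factorization",
    "exact_rank",
    "float_rank",
    "write_line_digraph",
]

#: Default ceiling on iterated-line-digraph size; past this, sparsify first.
DEFAULT_NODE_CEILING = 2_000_000


@dataclass(frozen=True)
class IncidencePair:
    """Head/tail incidence matrices H, T (n×m, one 1 per column each)."""

    H: sp.csr_array
    T: sp.csr_array


@dataclass(frozen=True)
class LineDigraph:
    """A line digraph (possibly iterated) with its parent-path bookkeeping.

    ``parent_map`` sends each line node to the directed path of base-graph
    nodes it represents: a pair (u, v) at level 1, a length-p path (p+1
    nodes) at level p.
    """

    graph: Digraph
    parent_map: dict[str, tuple[str, ...]]
    level: int

    @property
    def n(self) -> int:
        return self.graph.n

    @property
    def m(self) -> int:
        return self.graph.m


@dataclass(frozen=True)
class ClassFactorization:
    """The Ein/Eout/Q factorization certifying A_ℓG = Ein·Eout.

    Ein (m×n) indicates each edge's equivalence class, keyed by destination
    node; Eout (n×m) holds the distinct rows of A_ℓG; Q is the permutation
    with Qᵀ·Eout·Ein·Q = A_G (the identity under destination-node keying);
    EoutP is the row-substochastic analog of Eout carrying transition
    probabilities, EoutP[j, f] = T[j, f]/dout(j).
    """

    Ein: np.ndarray
    Eout: np.ndarray
    Q: np.ndarray
    EoutP: np.ndarray


def incidence_matrices(G: Digraph) -> IncidencePair:
    """Build the head (target) and tail (source) incidence matrices of G."""
    idx = G.node_index
    heads = [idx[v] for _, v in G.edges]
    tails = [idx[u] for u, _ in G.edges]
    cols = np.arange(G.m)
    ones = np.ones(G.m, dtype=np.int64)
    H = sp.csr_array((ones, (heads, cols)), shape=(G.n, G.m))
    T = sp.csr_array((ones, (tails, cols)), shape=(G.n, G.m))
    return IncidencePair(H=H, T=T)


def _line_node_name(path: tuple[str, ...]) -> str:
    return ">".join(path)


def line_digraph(G: Digraph) -> LineDigraph:
    """Construct ℓG: one node per edge of G, arcs between consecutive edges.

    Line nodes are ordered like the edges of G (lexicographic under the
    canonical order) and named ``src>dst``.  The adjacency of the result
    equals Hᵀ·T entrywise.
    """
    if G.m == 0:
        raise ValueError("line digraph of an edgeless graph is undefined")
    names = tuple(_line_node_name(e) for e in G.edges)
    parent_map = {name: e for name, e in zip(names, G.edges)}
    # successors of line node (u, v) are the edges whose tail is v
    out_edges: dict[str, list[int]] = {u: [] for u in G.nodes}
    for k, (u, _) in enumerate(G.edges):
        out_edges[u].append(k)
    line_edges = []
    for j, (_, v) in enumerate(G.edges):
        for k in out_edges[v]:
            line_edges.append((names[j], names[k]))
    graph = Digraph(nodes=names, edges=tuple(line_edges))
    return LineDigraph(graph=graph, parent_map=parent_map, level=1)


def iterate_line_digraph(
    G: Digraph, p: int, node_ceiling: int = DEFAULT_NODE_CEILING
) -> LineDigraph:
    """p-fold line digraph ℓᵖG; parent paths are directed length-p paths of G.

    Raises a size error (advising sparsification) if an intermediate graph
    would exceed ``node_ceiling`` nodes, and a ValueError if an intermediate
    graph runs out of edges.
    """
    if p < 1:
        raise ValueError("p must be a positive integer")
    current = line_digraph(G)
    for level in range(2, p + 1):
        if current.graph.m > node_ceiling:
            raise ValueError(
                f"iterated line digraph at level {level} would have "
                f"{current.graph.m} nodes (> ceiling {node_ceiling}); "
                "sparsify the input graph first"
            )
        nxt = line_digraph(current.graph)
        # rewrite compound names "x>y" (x, y line nodes of the previous
        # level) into base-graph paths; for a valid line arc the paths of x
        # and y overlap in all but their endpoints
        parent_map: dict[str, tuple[str, ...]] = {}
        rename: dict[str, str] = {}
        for name, (x, y) in nxt.parent_map.items():
            path = current.parent_map[x] + (current.parent_map[y][-1],)
            new = _line_node_name(path)
            parent_map[new] = path
            rename[name] = new
        nodes = tuple(rename[u] for u in nxt.graph.nodes)
        edges = tuple((rename[u], rename[v]) for u, v in nxt.graph.edges)
        current = LineDigraph(
            graph=Digraph(nodes=nodes, edges=edges),
            parent_map=parent_map,
            level=level,
        )
    return current


def inherit_labels(
    L: LineDigraph, node_labels: NodeLabeling, mode: str = "destination"
) -> NodeLabeling:
    """Label line nodes from their parent edge's destination (or source) node.

    A directed edge naturally inherits the class of the node it points to,
    which turns edge classification into a proxy for node classification;
    ``mode="source"`` uses the origin node instead.  For iterates the rule
    applies to the terminal (resp. initial) node of the parent path.
    """
    if mode not in ("destination", "source"):
        raise ValueError(f"mode must be 'destination' or 'source', got {mode!r}")
    pick = -1 if mode == "destination" else 0
    missing = sorted(
        {path[pick] for path in L.parent_map.values()} - set(node_labels.labels)
    )
    if missing:
        raise ValueError(f"unlabeled nodes referenced by line nodes: {missing}")
    mapping = {
        name: node_labels.labels[path[pick]] for name, path in L.parent_map.items()
    }
    return NodeLabeling(mapping)


def class_factorization(G: Digraph) -> ClassFactorization:
    """Group edges by destination node and factorize A_ℓG = Ein·Eout.

    With classes keyed by destination node in the canonical node order,
    Ein = Hᵀ and Eout = T exactly, so Eout·Ein = T·Hᵀ = A_G and Q is the
    identity.  The rank property behind this factorization assumes a
    strongly connected graph (no sinks, no sources); the identities
    themselves hold for any digraph, so graphs with sinks or sources only
    trigger a warning.
    """
    if G.m == 0:
        raise ValueError("cannot factorize an edgeless graph")
    if (G.out_degrees() == 0).any() or (G.in_degrees() == 0).any():
        warnings.warn(
            "graph has sinks or sources; the rank-n property assumes strong "
            "connectivity (the factorization identities still hold)",
            stacklevel=2,
        )
    pair = incidence_matrices(G)
    Ein = pair.H.T.toarray().astype(np.int64)
    Eout = pair.T.toarray().astype(np.int64)
    Q = np.eye(G.n, dtype=np.int64)
    dout = G.out_strengths()
    scale = np.divide(1.0, dout, out=np.zeros_like(dout), where=dout > 0)
    EoutP = Eout * scale[:, None] * G.edge_weights()[None, :]
    return ClassFactorization(Ein=Ein, Eout=Eout, Q=Q, EoutP=EoutP)


def exact_rank(M: np.ndarray) -> int:
    """Exact algebraic rank of an integer matrix over the rationals.

    Uses exact rational row reduction (no floating-point threshold), so a
    rank statement like rank(A_ℓG) = n is certified, not estimated.
    """
    A = np.asarray(M)
    if A.size == 0:
        return 0
    return int(sympy.Matrix(A.tolist()).rank())


def float_rank(M: np.ndarray, rtol: float = 1e-10) -> int:
    """SVD-based numerical rank with tolerance rtol·σ₁, for large matrices."""
    A = np.asarray(M, dtype=float)
    if A.size == 0:
        return 0
    s = np.linalg.svd(A, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int((s > rtol * s[0]).sum())


def write_line_digraph(L: LineDigraph, edge_dest, parent_dest=None) -> None:
    """Export ℓG as an edge-list TSV plus a sidecar parent-map TSV."""
    from .graph_core import write_edge_list, _as_text_stream

    write_edge_list(L.graph, edge_dest)
    if parent_dest is not None:
        stream, close = _as_text_stream(parent_dest, "w")
        try:
            for name in L.graph.nodes:
                path = "\t".join(L.parent_map[name])
                stream.write(f"{name}\t{path}\n")
        finally:
            if close:
                stream.close()
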