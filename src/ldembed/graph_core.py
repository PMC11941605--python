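"""Directed-graph data model, canonical ordering and edge-list I/O.

A :class:`Digraph` is a simple directed graph ``G = (V, E)`` with ``n = |V|``
nodes and ``m = |E|`` edges.  Node identifiers are opaque strings; every
matrix built elsewhere in the package uses 0-based dense integer indices
taken from the stored node order.  The canonical order — nodes sorted by
identifier, edges sorted lexicographically by (source index, target index) —
is the order in which the worked six-node example enumerates its edges
``e1=(a,b), …, e9=(f,e)``, and it is stable across file round-trips.

Files are plain TSV: one ``source<TAB>target[<TAB>weight]`` row per edge,
``#`` comments allowed; labels are ``node<TAB>label[,label…]`` rows.
Undirected inputs are symmetrized by adding both orientations.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Digraph",
    "NodeLabeling",
    "GraphFormatError",
    "GraphValidationError",
    "toy_digraph",
    "toy_labels",
    "canonical_order",
    "read_edge_list",
    "write_edge_list",
    "read_labels",
    "write_labels",
    "write_graphml",
]


class GraphFormatError(ValueError):
    """Malformed edge-list or label file (carries the offending line number)."""


class GraphValidationError(ValueError):
    """Structurally invalid graph (duplicate edge, unknown endpoint, bad weight)."""


@dataclass(frozen=True)
class Digraph:
    """A simple directed graph with optional edge weights and node labels.

    Parameters
    ----------
    nodes
        Ordered node identifiers.  The stored order defines matrix indices.
    edges
        Ordered ``(source, target)`` pairs.  Parallel edges are rejected;
        self-loops are accepted with a warning (they induce a self-loop in
        the line digraph).
    weights
        Optional per-edge positive weights, default 1 for every edge.
    labels
        Optional node labeling (see :class:`NodeLabeling`).
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    weights: tuple[float, ...] | None = None
    labels: "NodeLabeling | None" = None

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise GraphValidationError("duplicate node identifiers")
        node_set = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise GraphValidationError(f"edge ({u}, {v}) has endpoint outside the node set")
            if (u, v) in seen:
                raise GraphValidationError(f"duplicate edge ({u}, {v})")
            seen.add((u, v))
            if u == v:
                warnings.warn(f"self-loop at node {u!r}", stacklevel=3)
        if self.weights is not None:
            if len(self.weights) != len(self.edges):
                raise GraphValidationError("weights length does not match edge count")
            if any(w <= 0 for w in self.weights):
                raise GraphValidationError("edge weights must be positive")
        if self.labels is not None:
            missing = set(self.labels.labels) - node_set
            if missing:
                raise GraphValidationError(f"labeled nodes not in graph: {sorted(missing)}")

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def node_index(self) -> dict[str, int]:
        return {u: i for i, u in enumerate(self.nodes)}

    @property
    def edge_index(self) -> dict[tuple[str, str], int]:
        return {e: i for i, e in enumerate(self.edges)}

    def edge_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(self.m)
        return np.asarray(self.weights, dtype=float)

    # -- degrees and matrices --------------------------------------------

    def out_degrees(self) -> np.ndarray:
        """Unweighted out-degree vector, aligned with ``nodes``."""
        d = np.zeros(self.n, dtype=np.int64)
        idx = self.node_index
        for u, _ in self.edges:
            d[idx[u]] += 1
        return d

    def in_degrees(self) -> np.ndarray:
        """Unweighted in-degree vector, aligned with ``nodes``."""
        d = np.zeros(self.n, dtype=np.int64)
        idx = self.node_index
        for _, v in self.edges:
            d[idx[v]] += 1
        return d

    def out_strengths(self) -> np.ndarray:
        """Weighted out-degrees (row sums of the adjacency matrix)."""
        s = np.zeros(self.n)
        idx = self.node_index
        for (u, _), w in zip(self.edges, self.edge_weights()):
            s[idx[u]] += w
        return s

    def in_strengths(self) -> np.ndarray:
        s = np.zeros(self.n)
        idx = self.node_index
        for (_, v), w in zip(self.edges, self.edge_weights()):
            s[idx[v]] += w
        return s

    def adjacency(self, dense: bool = False) -> sp.csr_array | np.ndarray:
        """Weighted adjacency matrix A with A[i, j] = w(i, j)."""
        idx = self.node_index
        rows = [idx[u] for u, _ in self.edges]
        cols = [idx[v] for _, v in self.edges]
        A = sp.csr_array((self.edge_weights(), (rows, cols)), shape=(self.n, self.n))
        return A.toarray() if dense else A

    def volume(self) -> float:
        """vol(G) = sum of all edge weights (Σ_ij A_ij)."""
        return float(self.edge_weights().sum())

    def with_labels(self, labels: "NodeLabeling") -> "Digraph":
        return Digraph(self.nodes, self.edges, self.weights, labels)


@dataclass(frozen=True)
class NodeLabeling:
    """Map node → set of categorical labels; single-label is the |set| = 1 case."""

    labels: Mapping[str, frozenset[str]]

    @classmethod
    def from_single(cls, mapping: Mapping[str, str]) -> "NodeLabeling":
        return cls({u: frozenset([lab]) for u, lab in mapping.items()})

    @property
    def classes(self) -> tuple[str, ...]:
        out: set[str] = set()
        for labs in self.labels.values():
            out |= labs
        return tuple(sorted(out))

    @property
    def class_count(self) -> int:
        return len(self.classes)

    def is_single_label(self) -> bool:
        return all(len(labs) == 1 for labs in self.labels.values())

    def single(self, node: str) -> str:
        """The unique label of ``node`` (single-label graphs only)."""
        labs = self.labels[node]
        if len(labs) != 1:
            raise ValueError(f"node {node!r} carries {len(labs)} labels")
        return next(iter(labs))


# ---------------------------------------------------------------------------
# Fixture: the six-node worked example
# ---------------------------------------------------------------------------

def toy_digraph() -> Digraph:
    """Six-node, nine-edge example digraph used throughout the docs and tests.

    Nodes ``a..f``; edges in lexicographic order ``e1=(a,b), e2=(b,a),
    e3=(b,c), e4=(c,a), e5=(c,d), e6=(d,e), e7=(e,f), e8=(f,d), e9=(f,e)``.
    Its line digraph has 9 nodes and 12 edges, and the adjacency of the line
    digraph has exact rank 6 = n.
    """
    nodes = ("a", "b", "c", "d", "e", "f")
    edges = (
        ("a", "b"), ("b", "a"), ("b", "c"), ("c", "a"), ("c", "d"),
        ("d", "e"), ("e", "f"), ("f", "d"), ("f", "e"),
    )
    return Digraph(nodes, edges)


def toy_labels() -> NodeLabeling:
    """Two-community labeling of the toy graph: {a,b,c} blue, {d,e,f} green."""
    return NodeLabeling.from_single(
        {"a": "blue", "b": "blue", "c": "blue", "d": "green", "e": "green", "f": "green"}
    )


# ---------------------------------------------------------------------------
# Canonical order
# ---------------------------------------------------------------------------

def canonical_order(G: Digraph) -> Digraph:
    """Sort nodes by identifier and edges lexicographically; idempotent."""
    nodes = tuple(sorted(G.nodes))
    idx = {u: i for i, u in enumerate(nodes)}
    order = sorted(range(G.m), key=lambda k: (idx[G.edges[k][0]], idx[G.edges[k][1]]))
    edges = tuple(G.edges[k] for k in order)
    weights = None
    if G.weights is not None:
        weights = tuple(G.weights[k] for k in order)
    return Digraph(nodes, edges, weights, G.labels)


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def _as_text_stream(source: str | Path | IO[str], mode: str = "r") -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


def read_edge_list(source: str | Path | IO[str], symmetrize: bool = False) -> Digraph:
    """Parse a ``src<TAB>dst[<TAB>weight]`` edge list into a canonical Digraph.

    Fields may be separated by tabs or spaces; lines starting with ``#`` are
    ignored.  With ``symmetrize=True`` an undirected input is converted to a
    digraph by adding both orientations of every edge.

    Raises
    ------
    GraphFormatError
        On a malformed row (with its line number) or a duplicate edge row.
    GraphValidationError
        On a non-positive weight.
    """
    stream, close = _as_text_stream(source)
    edges: list[tuple[str, str]] = []
    weights: dict[tuple[str, str], float] = {}
    any_weight = False
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise GraphFormatError(f"line {lineno}: expected 2 or 3 fields, got {len(parts)}")
            u, v = parts[0], parts[1]
            w = 1.0
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise GraphFormatError(f"line {lineno}: bad weight {parts[2]!r}") from exc
                if w <= 0:
                    raise GraphValidationError(f"line {lineno}: non-positive weight {w}")
                any_weight = True
            if (u, v) in weights:
                raise GraphFormatError(f"line {lineno}: duplicate edge ({u}, {v})")
            edges.append((u, v))
            weights[(u, v)] = w
    finally:
        if close:
            stream.close()

    if symmetrize:
        for u, v in list(edges):
            if (v, u) not in weights:
                edges.append((v, u))
                weights[(v, u)] = weights[(u, v)]

    nodes = tuple(sorted({x for e in edges for x in e}))
    wtuple = tuple(weights[e] for e in edges) if any_weight else None
    return canonical_order(Digraph(nodes, tuple(edges), wtuple))


def write_edge_list(G: Digraph, dest: str | Path | IO[str] | None = None) -> str | None:
    """Write the edge list as TSV; returns the text when ``dest`` is None."""
    buf = io.StringIO()
    weighted = G.weights is not None
    for k, (u, v) in enumerate(G.edges):
        if weighted:
            w = G.weights[k]
            wtxt = repr(int(w)) if float(w).is_integer() else repr(w)
            buf.write(f"{u}\t{v}\t{wtxt}\n")
        else:
            buf.write(f"{u}\t{v}\n")
    text = buf.getvalue()
    if dest is None:
        return text
    stream, close = _as_text_stream(dest, "w")
    try:
        stream.write(text)
    finally:
        if close:
            stream.close()
    return None


def read_labels(source: str | Path | IO[str]) -> NodeLabeling:
    """Parse ``node<TAB>label[,label…]`` rows into a NodeLabeling."""
    stream, close = _as_text_stream(source)
    mapping: dict[str, frozenset[str]] = {}
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise GraphFormatError(f"line {lineno}: expected 'node<TAB>labels'")
            node, labs = parts
            labels = frozenset(s.strip() for s in labs.split(",") if s.strip())
            if not labels:
                raise GraphFormatError(f"line {lineno}: empty label set for {node!r}")
            if node in mapping:
                raise GraphFormatError(f"line {lineno}: duplicate node {node!r}")
            mapping[node] = labels
    finally:
        if close:
            stream.close()
    return NodeLabeling(mapping)


def write_labels(L: NodeLabeling, dest: str | Path | IO[str] | None = None) -> str | None:
    buf = io.StringIO()
    for node in sorted(L.labels):
        buf.write(f"{node}\t{','.join(sorted(L.labels[node]))}\n")
    text = buf.getvalue()
    if dest is None:
        return text
    stream, close = _as_text_stream(dest, "w")
    try:
        stream.write(text)
    finally:
        if close:
            stream.close()
    return None


def write_graphml(G: Digraph, dest: str | Path | IO[str]) -> None:
    """Minimal GraphML export for external visualization tools."""
    import xml.etree.ElementTree as ET

    root = ET.Element("graphml", xmlns="http://graphml.graphdrawing.org/xmlns")
    g = ET.SubElement(root, "graph", id="G", edgedefault="directed")
    for u in G.nodes:
        ET.SubElement(g, "node", id=u)
    for u, v in G.edges:
        ET.SubElement(g, "edge", source=u, target=v)
    text = ET.tostring(root, encoding="unicode", xml_declaration=True)
    stream, close = _as_text_stream(dest, "w")
    try:
        stream.write(text)
    finally:
        if close:
            stream.close()
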