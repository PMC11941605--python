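"""Matrix-factorization embeddings (NetMF-style), Katz similarity, and
random-walk occupancy diagnostics.

The similarity matrix to factorize is

    M = (vol(G)/b) · S,        S = (1/T) Σ_{r=1..T} Pʳ D⁻¹,

with P the out-degree transition matrix, D the out-degree diagonal, T the
skip-gram window size and b the negative-sampling parameter.  Embeddings
are the top-d left singular vectors of M̂ = log(max(M, 1)), scaled by the
square roots of the singular values; the right factor is exposed as
"context" vectors (the asymmetric-role treatment natural for digraphs).

Applied to a line digraph, the linearity identity turns each entry of M_ℓG
into a weighted combination of n node-to-node walk probabilities
(:func:`line_similarity_entry`); edges sharing a destination node receive
identical rows of S_ℓG, so the pre-log similarity has at most n distinct
rows — the rank-preservation property that keeps line-digraph embeddings
informative at any m.

Katz similarity K = Σ_{r≤T} βʳ Aʳ (the HOPE kernel) is included for edge
mining; it converges for β·λ₁ < 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph_core import Digraph
from .linegraph import class_factorization, line_digraph
from .spectral import transition_matrix

__all__ = [
    "EmbedConfig",
    "EmbeddingResult",
    "OccupancyProfile",
    "netmf_similarity",
    "log_clip",
    "svd_embed",
    "embed_graph",
    "line_similarity_entry",
    "katz_similarity",
    "katz_line_factorized",
    "occupancy_histogram",
    "spectral_radius",
    "write_embedding",
]


@dataclass(frozen=True)
class EmbedConfig:
    """Embedding hyperparameters.

    window
        Skip-gram window size T (number of walk powers averaged); default 10.
    b
        Negative-sampling parameter; default 1.
    dim
        Embedding dimension d; default 128 (truncated to the matrix size
        with a warning when larger).
    beta
        Katz decay β; default 0.1, must satisfy β·λ₁ < 1.
    """

    window: int = 10
    b: float = 1.0
    dim: int = 128
    beta: float = 0.1

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be ≥ 1")
        if self.b <= 0:
            raise ValueError("b must be positive")
        if self.dim < 1:
            raise ValueError("dim must be ≥ 1")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")


@dataclass(frozen=True)
class EmbeddingResult:
    """Similarity matrix, its log-clipped form, and the SVD embedding."""

    basis: tuple[str, ...]
    M: np.ndarray
    M_hat: np.ndarray
    singular_values: np.ndarray
    vectors: np.ndarray          # rows: U_d·√Σ_d
    context_vectors: np.ndarray  # rows: V_d·√Σ_d

    @property
    def singular_gap(self) -> float:
        """σ₁ − σ₂ of M̂ (0 for a 1×1 matrix)."""
        s = self.singular_values
        return float(s[0] - s[1]) if s.size >= 2 else float(s[0]) if s.size else 0.0


@dataclass(frozen=True)
class OccupancyProfile:
    """Node-visit statistics of seeded simple random walks."""

    basis: tuple[str, ...]
    counts: np.ndarray
    unreached_fraction: float
    normalized_entropy: float


def netmf_similarity(G: Digraph, cfg: EmbedConfig | None = None) -> np.ndarray:
    """M = (vol(G)/b)·(1/T)·Σ_{r=1..T} Pʳ·D⁻¹ with sink columns of D⁻¹ zero."""
    cfg = cfg or EmbedConfig()
    P = transition_matrix(G).P
    dout = G.out_strengths()
    dinv = np.divide(1.0, dout, out=np.zeros_like(dout), where=dout > 0)
    S = np.zeros_like(P)
    Pr = np.eye(G.n)
    for _ in range(cfg.window):
        Pr = Pr @ P
        S += Pr
    S = (S / cfg.window) * dinv[None, :]
    return (G.volume() / cfg.b) * S


def log_clip(M: np.ndarray) -> np.ndarray:
    """M̂ = log(max(M, 1)) elementwise (natural log, so M̂ ≥ 0)."""
    return np.log(np.maximum(M, 1.0))


def svd_embed(
    M_hat: np.ndarray,
    d: int,
    basis: tuple[str, ...] | None = None,
    M: np.ndarray | None = None,
) -> EmbeddingResult:
    """Top-d SVD of M̂; embedding rows are U_d·√Σ_d, contexts V_d·√Σ_d."""
    n = M_hat.shape[0]
    if d > n:
        warnings.warn(f"requested dimension {d} exceeds matrix size {n}; truncating")
        d = n
    U, s, Vt = np.linalg.svd(M_hat, full_matrices=False)
    root = np.sqrt(s[:d])
    return EmbeddingResult(
        basis=basis if basis is not None else tuple(str(i) for i in range(n)),
        M=M if M is not None else M_hat,
        M_hat=M_hat,
        singular_values=s,
        vectors=U[:, :d] * root[None, :],
        context_vectors=Vt[:d, :].T * root[None, :],
    )


def embed_graph(G: Digraph, cfg: EmbedConfig | None = None) -> EmbeddingResult:
    """NetMF pipeline: similarity → log-clip → truncated SVD embedding."""
    cfg = cfg or EmbedConfig()
    M = netmf_similarity(G, cfg)
    return svd_embed(log_clip(M), cfg.dim, basis=G.nodes, M=M)


def line_similarity_entry(G: Digraph, ei, ej, cfg: EmbedConfig | None = None) -> float:
    """Entry (ei, ej) of M_ℓG computed through the factorized inner sum.

    Uses the linearity identity to express the r-step edge-to-edge walk
    probabilities as combinations of node-to-node ones:

        M_ℓG(ei, ej) = (vol(ℓG)/(b·dout_ℓG(ej)))·(1/T)·Σ_r Σ_k α_ik P̄^{r−1}(ei⁻, ek⁻)

    and must equal the same entry of ``netmf_similarity(line_digraph(G))``.
    The degree normalization is the out-degree of the column line-node ej
    (the D⁻¹ factor of the NetMF matrix acts on columns).
    """
    from .spectral import _edge_id_to_index

    cfg = cfg or EmbedConfig()
    L = line_digraph(G)
    i, j = _edge_id_to_index(L, ei), _edge_id_to_index(L, ej)
    dout_j = L.graph.out_strengths()[j]
    if dout_j == 0:
        return 0.0
    cf = class_factorization(G)
    P = transition_matrix(G).P
    Pbar = cf.Q @ P @ cf.Q.T
    head_i = G.node_index[G.edges[i][1]]
    total = 0.0
    row = np.zeros(G.n)
    row[head_i] = 1.0  # P̄⁰ row
    for _ in range(cfg.window):
        total += float(row @ cf.EoutP[:, j])
        row = row @ Pbar
    return (L.graph.volume() / (cfg.b * dout_j)) * total / cfg.window


def spectral_radius(A: np.ndarray) -> float:
    """Largest eigenvalue magnitude of a square matrix."""
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(A, dtype=float)))))


def katz_similarity(A: np.ndarray, beta: float, T: int) -> np.ndarray:
    """Truncated Katz matrix K = Σ_{r=1..T} βʳ·Aʳ; requires β·λ₁ < 1."""
    A = np.asarray(A, dtype=float)
    lam = spectral_radius(A)
    if beta * lam >= 1.0:
        raise ValueError(
            f"Katz series diverges: beta·lambda1 = {beta * lam:.4g} ≥ 1"
        )
    K = np.zeros_like(A)
    Pr = np.eye(A.shape[0])
    scale = 1.0
    for _ in range(T):
        Pr = Pr @ A
        scale *= beta
        K += scale * Pr
    return K


def katz_line_factorized(G: Digraph, beta: float, T: int) -> np.ndarray:
    """Katz matrix of ℓG via the factorized route Σ_r βʳ·Ein·Ā^{r−1}·Eout.

    A_ℓGʳ = Ein·A_G^{r−1}·Eout (the unnormalized analog of the linearity
    identity), so paths between edges of G are linear combinations of the
    corresponding node paths.  Agrees with ``katz_similarity`` applied to
    the line-digraph adjacency.
    """
    A = G.adjacency(dense=True)
    lam = spectral_radius(A)
    if beta * lam >= 1.0:
        raise ValueError(
            f"Katz series diverges: beta·lambda1 = {beta * lam:.4g} ≥ 1"
        )
    cf = class_factorization(G)
    Abar = (cf.Q @ A @ cf.Q.T)
    K = np.zeros((G.m, G.m))
    Ar = np.eye(G.n)
    scale = 1.0
    for _ in range(T):
        scale *= beta
        K += scale * (cf.Ein @ Ar @ cf.Eout)
        Ar = Ar @ Abar
    return K


def occupancy_histogram(
    G: Digraph,
    walks_per_node: int = 10,
    walk_length: int = 80,
    seed: int = 0,
    start_nodes: tuple[str, ...] | None = None,
) -> OccupancyProfile:
    """Visit counts of seeded simple random walks (the long-tail diagnostic).

    Launches ``walks_per_node`` walks of ``walk_length`` steps from every
    node (or from ``start_nodes``), following out-edges with probability
    proportional to weight and truncating at sinks.  Occurrences are counted
    at steps 1..L (start positions are not counted, so never-reached nodes
    show up in ``unreached_fraction``).  ``normalized_entropy`` is the
    Shannon entropy of the visit distribution divided by log(n); a heavier
    long tail means lower entropy.
    """
    if walks_per_node < 1 or walk_length < 1:
        raise ValueError("walk parameters must be positive")
    rng = np.random.default_rng(seed)
    idx = G.node_index
    succ: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(G.n)]
    cump: list[np.ndarray] = [np.empty(0) for _ in range(G.n)]
    tmp: dict[int, list[tuple[int, float]]] = {i: [] for i in range(G.n)}
    for (u, v), w in zip(G.edges, G.edge_weights()):
        tmp[idx[u]].append((idx[v], w))
    for i, lst in tmp.items():
        if lst:
            succ[i] = np.array([t for t, _ in lst], dtype=np.int64)
            p = np.array([w for _, w in lst])
            cump[i] = np.cumsum(p / p.sum())
    counts = np.zeros(G.n, dtype=np.int64)
    starts = (
        [idx[u] for u in start_nodes] if start_nodes is not None else list(range(G.n))
    )
    for s in starts:
        for _ in range(walks_per_node):
            cur = s
            draws = rng.random(walk_length)
            for step in range(walk_length):
                if succ[cur].size == 0:
                    break
                cur = int(succ[cur][np.searchsorted(cump[cur], draws[step])])
                counts[cur] += 1
    total = counts.sum()
    if total > 0:
        p = counts[counts > 0] / total
        entropy = float(-(p * np.log(p)).sum())
        norm_entropy = entropy / np.log(G.n) if G.n > 1 else 1.0
    else:
        norm_entropy = 0.0
    return OccupancyProfile(
        basis=G.nodes,
        counts=counts,
        unreached_fraction=float((counts == 0).mean()),
        normalized_entropy=float(norm_entropy),
    )


def write_embedding(result: EmbeddingResult, dest) -> None:
    """Save embeddings as TSV: entity id then d tab-separated floats."""
    from .graph_core import _as_text_stream

    stream, close = _as_text_stream(dest, "w")
    try:
        for name, row in zip(result.basis, result.vectors):
            vals = "\t".join(repr(float(x)) for x in row)
            stream.write(f"{name}\t{vals}\n")
    finally:
        if close:
            stream.close()
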