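"""Random-walk and spectral diagnostics relating G to its line digraph ℓG.

A_G and A_ℓG share their non-zero spectrum with multiplicities (a Flanders
pair), and so do the out-degree-normalized transition matrices
P_G = D_G⁻¹A_G and P_ℓG = D_ℓG⁻¹A_ℓG.  Consequences implemented here:

* tr(P_ℓGʳ) = tr(P_Gʳ) for every r, hence the expected return probabilities
  E_G(r) = tr(P_Gʳ)/n and E_ℓG(r) = tr(P_ℓGʳ)/m satisfy n·E_G(r) = m·E_ℓG(r).
  Since m ≥ n, walks on ℓG return less often — they diffuse further, which
  is the quasi-maximum-entropy argument for embedding the line digraph.
* The linearity identity P_ℓGʳ = Ein·P̄^{r−1}·EoutP: every entry of the
  r-step edge-to-edge transition matrix is a linear combination of n
  (r−1)-step node-to-node transitions.  P̄ = Q·P_G·Qᵀ is the class-order
  permutation of P_G (the identity under destination-node keying).
* Moore-type order bounds (λ₁^{D+1}−1)/(λ₁−1) for G and exponent D+2 for ℓG.
* HITS hub/authority scores; applied to ℓG they rank edge-hubs and
  edge-authorities.

Rows of sink nodes are kept identically zero (substochastic) rather than
patched with teleportation, so the operator is never silently altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graph_core import Digraph
from .linegraph import LineDigraph, class_factorization, line_digraph

__all__ = [
    "TransitionMatrix",
    "ReturnProfile",
    "TraceCheck",
    "HITSResult",
    "transition_matrix",
    "return_probability",
    "return_profile_pair",
    "trace_spectrum_check",
    "edge_similarity_entry",
    "linearity_check",
    "moore_bound",
    "hits_scores",
    "distinct_row_count",
]

#: Dense matrix powers are used below this size; larger graphs fall back to
#: Hutchinson-style stochastic trace estimation.
DENSE_TRACE_LIMIT = 2000


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-substochastic walk operator P = D⁻¹A with sink rows zero."""

    P: np.ndarray
    basis: tuple[str, ...]
    sink_rows: tuple[int, ...]

    @property
    def size(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class ReturnProfile:
    """Expected probability of an r-step walk returning to its start."""

    r: int
    trace: float
    expected_return: float


@dataclass(frozen=True)
class TraceCheck:
    """Flanders-pair diagnostic for (G, ℓG) over r = 1..rmax."""

    rmax: int
    max_trace_discrepancy: float
    max_ratio_residual: float  # max_r |n·E_G(r) − m·E_ℓG(r)|
    eigenvalues_match: bool


@dataclass(frozen=True)
class HITSResult:
    hub: np.ndarray
    authority: np.ndarray
    iterations: int
    converged: bool


def transition_matrix(G: Digraph) -> TransitionMatrix:
    """P[i, j] = w(i, j)/dout(i); rows of out-degree-0 nodes stay zero."""
    A = G.adjacency(dense=True)
    dout = G.out_strengths()
    sinks = tuple(int(i) for i in np.flatnonzero(dout == 0))
    scale = np.divide(1.0, dout, out=np.zeros_like(dout), where=dout > 0)
    return TransitionMatrix(P=A * scale[:, None], basis=G.nodes, sink_rows=sinks)


def return_probability(P: TransitionMatrix, r: int) -> ReturnProfile:
    """E(r) = tr(Pʳ)/size, the expected return probability after r steps."""
    if r < 1:
        raise ValueError("r must be a positive integer")
    tr = float(np.trace(np.linalg.matrix_power(P.P, r)))
    return ReturnProfile(r=r, trace=tr, expected_return=tr / P.size)


def return_profile_pair(G: Digraph, r: int) -> dict[str, float]:
    """Return probabilities of G and ℓG at step r plus the ratio residual.

    The residual |n·E_G(r) − m·E_ℓG(r)| is zero in exact arithmetic by the
    trace equality of the Flanders pair.
    """
    lG = line_digraph(G).graph
    pg = return_probability(transition_matrix(G), r)
    pl = return_probability(transition_matrix(lG), r)
    return {
        "r": float(r),
        "tr_G": pg.trace,
        "tr_lG": pl.trace,
        "E_G": pg.expected_return,
        "E_lG": pl.expected_return,
        "ratio_residual": abs(G.n * pg.expected_return - G.m * pl.expected_return),
    }


def _stochastic_trace(P: np.ndarray, r: int, n_probes: int, rng: np.random.Generator) -> float:
    # Hutchinson estimator with Rademacher probes: E[zᵀPʳz] = tr(Pʳ)
    n = P.shape[0]
    Z = rng.choice([-1.0, 1.0], size=(n, n_probes))
    W = Z.copy()
    for _ in range(r):
        W = P @ W
    return float(np.einsum("ij,ij->j", Z, W).mean())


def trace_spectrum_check(
    G: Digraph,
    rmax: int,
    eig_tol: float = 1e-6,
    n_probes: int = 64,
    seed: int = 0,
) -> TraceCheck:
    """Verify tr(P_ℓGʳ) = tr(P_Gʳ) for r ≤ rmax and the non-zero spectra match.

    Eigenvalue multisets are compared after magnitude sort by greedy pairing
    within ``eig_tol``.  Graphs above ``DENSE_TRACE_LIMIT`` nodes use seeded
    stochastic trace estimation instead of dense powers.
    """
    lG = line_digraph(G).graph
    PG = transition_matrix(G).P
    PL = transition_matrix(lG).P
    rng = np.random.default_rng(seed)
    max_disc = 0.0
    max_ratio = 0.0
    MG, ML = np.eye(G.n), np.eye(lG.n)
    for r in range(1, rmax + 1):
        if max(G.n, lG.n) <= DENSE_TRACE_LIMIT:
            MG, ML = MG @ PG, ML @ PL
            tg, tl = float(np.trace(MG)), float(np.trace(ML))
        else:
            tg = _stochastic_trace(PG, r, n_probes, rng)
            tl = _stochastic_trace(PL, r, n_probes, rng)
        max_disc = max(max_disc, abs(tg - tl))
        # n·E_G(r) = tr and m·E_ℓG(r) = tr as well, so the residual is the same
        max_ratio = max(max_ratio, abs(G.n * (tg / G.n) - lG.n * (tl / lG.n)))

    eig_ok = True
    if max(G.n, lG.n) <= DENSE_TRACE_LIMIT:
        ev_g = np.linalg.eigvals(G.adjacency(dense=True))
        ev_l = np.linalg.eigvals(lG.adjacency(dense=True))
        nz_g = sorted(ev_g[np.abs(ev_g) > eig_tol], key=abs, reverse=True)
        nz_l = sorted(ev_l[np.abs(ev_l) > eig_tol], key=abs, reverse=True)
        if len(nz_g) != len(nz_l):
            eig_ok = False
        else:
            remaining = list(nz_l)
            for lam in nz_g:
                hit = next(
                    (i for i, mu in enumerate(remaining) if abs(lam - mu) <= eig_tol),
                    None,
                )
                if hit is None:
                    eig_ok = False
                    break
                remaining.pop(hit)
    return TraceCheck(
        rmax=rmax,
        max_trace_discrepancy=max_disc,
        max_ratio_residual=max_ratio,
        eigenvalues_match=eig_ok,
    )


def _edge_id_to_index(L: LineDigraph, e) -> int:
    """Resolve an edge id: an index, a (src, dst) pair, or a 'src>dst' name."""
    if isinstance(e, (int, np.integer)):
        if not 0 <= e < L.n:
            raise KeyError(f"edge index {e} out of range")
        return int(e)
    if isinstance(e, tuple):
        name = ">".join(e)
    else:
        name = str(e)
    idx = L.graph.node_index
    if name not in idx:
        raise KeyError(f"unknown edge id {e!r}")
    return idx[name]


def _warn_if_not_strong(G: Digraph) -> None:
    if (G.out_degrees() == 0).any() or (G.in_degrees() == 0).any():
        warnings.warn(
            "graph has sinks or sources; the linearity identity assumes a "
            "strongly connected digraph",
            stacklevel=3,
        )


def edge_similarity_entry(G: Digraph, ei, ej, r: int) -> float:
    """P_ℓGʳ(ei, ej) via the factorized route Σ_k α_ik·P̄^{r−1}(ei⁻, ek⁻).

    ``ei⁻`` is the destination node of edge ei, and α_ik = P_ℓG(ek, ej) is
    the one-step line-digraph transition out of class k, i.e. EoutP[k, ej]
    under destination-node keying.  Must agree with the (ei, ej) entry of
    the direct r-th power of P_ℓG.
    """
    if r < 1:
        raise ValueError("r must be ≥ 1")
    _warn_if_not_strong(G)
    L = line_digraph(G)
    i, j = _edge_id_to_index(L, ei), _edge_id_to_index(L, ej)
    cf = class_factorization(G)
    P = transition_matrix(G).P
    Pbar = cf.Q @ P @ cf.Q.T
    head_i = G.node_index[G.edges[i][1]]
    row = np.linalg.matrix_power(Pbar, r - 1)[head_i, :]
    return float(row @ cf.EoutP[:, j])


def distinct_row_count(M: np.ndarray, tol: float = 1e-9) -> int:
    """Number of distinct rows of M, comparing entries within tol."""
    rows = [M[0]]
    for row in M[1:]:
        if not any(np.allclose(row, seen, atol=tol, rtol=0.0) for seen in rows):
            rows.append(row)
    return len(rows)


def linearity_check(G: Digraph, r: int) -> tuple[float, int]:
    """Max residual of Ein·P̄^{r−1}·EoutP vs P_ℓGʳ, and distinct rows of P_ℓGʳ.

    The residual is zero (to rounding) by the linearity identity; the
    distinct-row count is at most n because Ein has only n distinct rows.
    """
    if r < 1:
        raise ValueError("r must be ≥ 1")
    cf = class_factorization(G)
    P = transition_matrix(G).P
    Pbar = cf.Q @ P @ cf.Q.T
    lhs = cf.Ein @ np.linalg.matrix_power(Pbar, r - 1) @ cf.EoutP
    PL = transition_matrix(line_digraph(G).graph).P
    rhs = np.linalg.matrix_power(PL, r)
    residual = float(np.max(np.abs(lhs - rhs)))
    return residual, distinct_row_count(rhs)


def moore_bound(lambda1: float, D: int, line: bool = False) -> float:
    """Moore-type order bound (λ₁^{D+1}−1)/(λ₁−1); exponent D+2 for ℓG.

    λ₁ is the leading adjacency eigenvalue (shared by G and ℓG) and D the
    diameter of G.  At λ₁ = 1 the geometric sum degenerates; the limit value
    (D+1, resp. D+2) is returned.
    """
    if lambda1 <= 0:
        raise ValueError("lambda1 must be positive")
    if D < 1:
        raise ValueError("D must be a positive integer")
    e = D + 2 if line else D + 1
    if abs(lambda1 - 1.0) < 1e-12:
        return float(e)
    return float((lambda1**e - 1.0) / (lambda1 - 1.0))


def hits_scores(
    G: Digraph, tol: float = 1e-10, max_iter: int = 1000
) -> HITSResult:
    """Mutually reinforcing hub/authority power iteration, L2-normalized.

    h ∝ A·a and a ∝ Aᵀ·h; on a line digraph the scores rank edge-hubs and
    edge-authorities of the base graph.  Non-convergence within ``max_iter``
    is flagged rather than raised.
    """
    if G.n == 0:
        raise ValueError("empty graph")
    A = G.adjacency(dense=True)
    a = np.full(G.n, 1.0 / np.sqrt(G.n))
    h = np.full(G.n, 1.0 / np.sqrt(G.n))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        h_new = A @ a
        nh = np.linalg.norm(h_new)
        h_new = h_new / nh if nh > 0 else h_new
        a_new = A.T @ h_new
        na = np.linalg.norm(a_new)
        a_new = a_new / na if na > 0 else a_new
        if max(np.max(np.abs(h_new - h)), np.max(np.abs(a_new - a))) < tol:
            h, a = h_new, a_new
            converged = True
            break
        h, a = h_new, a_new
    if not converged:
        warnings.warn(f"HITS did not converge in {max_iter} iterations", stacklevel=2)
    return HITSResult(hub=h, authority=a, iterations=it, converged=converged)
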