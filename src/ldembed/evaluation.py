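"""Node-proxy classification and clustering protocols with stability sweeps.

Classification follows the standard embedding benchmark: a logistic
regression (one-vs-rest, L2, strength 1.0, 500 iterations) is trained on a
stratified 50% split of the embedded entities and scored by micro/macro F1
on the held-out half; multi-label entities are scored by predicting as many
labels as they truly carry, ranked by classifier score.  On a line digraph
the entities are edges labeled by their destination node, so edge
classification doubles as a node-classification proxy (a majority vote over
each node's in-edges maps predictions back to nodes).

Clustering is bottom-up agglomerative (Ward linkage on Euclidean distance)
cut at C clusters, evaluated by the Adjusted Rand Index against the label
partition and by directed modularity

    Q(A) = (1/W) Σ_{C∈P} Σ_{i,j∈C} [A_ij − dout(i)·din(j)/W],    W = Σ_ij A_ij,

the directed null model in which edge (i, j) is expected with probability
dout(i)·din(j)/W.

:func:`stability_curve` sweeps the inverse degree of sparsification z:
sparsify → build representation (graph, line digraph, or second iterate) →
embed → evaluate, fully reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score, f1_score
from sklearn.multiclass import OneVsRestClassifier
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import MultiLabelBinarizer

from .graph_core import Digraph, NodeLabeling
from .embedding import EmbedConfig, EmbeddingResult, embed_graph
from .linegraph import inherit_labels, iterate_line_digraph, line_digraph
from .sparsify import sparsify

__all__ = [
    "Partition",
    "EvalReport",
    "classify_protocol",
    "cluster_protocol",
    "adjusted_rand_index",
    "directed_modularity",
    "labels_to_partition",
    "node_proxy_f1",
    "stability_curve",
]


@dataclass(frozen=True)
class Partition:
    """Assignment of every entity to exactly one cluster id."""

    assignment: Mapping[str, int]

    @property
    def cluster_count(self) -> int:
        return len(set(self.assignment.values()))

    def vector(self, basis: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[u] for u in basis], dtype=np.int64)


@dataclass(frozen=True)
class EvalReport:
    """One evaluation outcome, annotated with the sparsification level."""

    task: str
    z: float
    micro_f1: float | None = None
    macro_f1: float | None = None
    ari: float | None = None
    modularity_pred: float | None = None
    modularity_true: float | None = None
    singular_gap: float | None = None


def _label_matrix(
    labels: NodeLabeling, basis: Sequence[str]
) -> tuple[np.ndarray, MultiLabelBinarizer]:
    mlb = MultiLabelBinarizer(classes=list(labels.classes))
    Y = mlb.fit_transform([sorted(labels.labels[u]) for u in basis])
    return Y, mlb


def classify_protocol(
    embedding: EmbeddingResult,
    labels: NodeLabeling,
    train_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[float, float]:
    """Train/test a one-vs-rest logistic regression; return (micro, macro) F1.

    The split is stratified by label (single-label case) and seeded.  A
    class entirely missing from the training half raises with a hint to try
    another seed.
    """
    X = embedding.vectors
    basis = embedding.basis
    missing = [u for u in basis if u not in labels.labels]
    if missing:
        raise ValueError(f"unlabeled entities: {missing[:5]}{'…' if len(missing) > 5 else ''}")
    Y, _ = _label_matrix(labels, basis)
    single = labels.is_single_label()
    y_flat = Y.argmax(axis=1) if single else None
    idx = np.arange(len(basis))
    try:
        train, test = train_test_split(
            idx,
            train_size=train_fraction,
            random_state=seed,
            stratify=y_flat if single else None,
        )
    except ValueError as exc:
        raise ValueError(
            f"cannot form a stratified split ({exc}); try another seed or "
            "a larger train fraction"
        ) from exc
    present = Y[train].sum(axis=0) > 0
    if not present.all():
        absent = [c for c, ok in zip(labels.classes, present) if not ok]
        raise ValueError(
            f"classes absent from the training split: {absent}; try another seed"
        )
    clf = OneVsRestClassifier(LogisticRegression(C=1.0, max_iter=500))
    clf.fit(X[train], Y[train])
    scores = clf.decision_function(X[test])
    scores = np.atleast_2d(scores)
    if scores.shape[1] == 1 and Y.shape[1] == 2:  # binary decision_function
        scores = np.hstack([-scores, scores])
    # predict exactly as many labels as each entity truly has, by rank
    Y_pred = np.zeros_like(Y[test])
    k_true = Y[test].sum(axis=1)
    for row, (s, k) in enumerate(zip(scores, k_true)):
        top = np.argsort(s)[::-1][: int(k)]
        Y_pred[row, top] = 1
    micro = f1_score(Y[test], Y_pred, average="micro", zero_division=0)
    macro = f1_score(Y[test], Y_pred, average="macro", zero_division=0)
    return float(micro), float(macro)


def cluster_protocol(
    embedding: EmbeddingResult, C: int, linkage: str = "ward"
) -> Partition:
    """Agglomerative clustering of the embedding vectors, cut at C clusters."""
    if C < 2:
        raise ValueError("C must be ≥ 2")
    if C > len(embedding.basis):
        raise ValueError(f"C = {C} exceeds entity count {len(embedding.basis)}")
    model = AgglomerativeClustering(n_clusters=C, linkage=linkage)
    ids = model.fit_predict(embedding.vectors)
    return Partition({u: int(c) for u, c in zip(embedding.basis, ids)})


def adjusted_rand_index(a: Partition, b: Partition) -> float:
    """Permutation-model ARI between two partitions of the same entity set."""
    if set(a.assignment) != set(b.assignment):
        raise ValueError("partitions cover different entity sets")
    basis = sorted(a.assignment)
    return float(adjusted_rand_score(a.vector(basis), b.vector(basis)))


def labels_to_partition(labels: NodeLabeling, basis: Sequence[str]) -> Partition:
    """Ground-truth partition from a single-label labeling."""
    classes = {c: i for i, c in enumerate(labels.classes)}
    return Partition({u: classes[labels.single(u)] for u in basis})


def directed_modularity(G: Digraph, part: Partition) -> float:
    """Directed modularity Q of a node partition of G.

    Q = (1/W)·Σ_C [ w(C→C) − dout(C)·din(C)/W ] where w(C→C) is the total
    weight of intra-community edges and dout(C), din(C) are community
    out-/in-strength sums.  Q = 0 exactly for the single-community
    partition.
    """
    if G.n == 0:
        raise ValueError("empty graph")
    missing = set(G.nodes) - set(part.assignment)
    if missing:
        raise ValueError(f"partition misses nodes: {sorted(missing)[:5]}")
    W = G.volume()
    if W <= 0:
        raise ValueError("graph has zero volume")
    comm = part.vector(G.nodes)
    ncomm = comm.max() + 1
    dout = G.out_strengths()
    din = G.in_strengths()
    intra = np.zeros(ncomm)
    idx = G.node_index
    for (u, v), w in zip(G.edges, G.edge_weights()):
        cu, cv = comm[idx[u]], comm[idx[v]]
        if cu == cv:
            intra[cu] += w
    dout_c = np.bincount(comm, weights=dout, minlength=ncomm)
    din_c = np.bincount(comm, weights=din, minlength=ncomm)
    return float((intra - dout_c * din_c / W).sum() / W)


def node_proxy_f1(
    G: Digraph,
    edge_partition_or_labels: Mapping[str, str],
    node_labels: NodeLabeling,
) -> float:
    """Micro-F1 of node labels recovered by majority vote over in-edges.

    ``edge_partition_or_labels`` maps line-node names ('u>v') to predicted
    labels; each node of G takes the most frequent prediction among its
    in-edges (ties broken lexicographically; nodes without in-edges are
    skipped).
    """
    votes: dict[str, dict[str, int]] = {}
    for u, v in G.edges:
        name = f"{u}>{v}"
        if name not in edge_partition_or_labels:
            continue
        lab = edge_partition_or_labels[name]
        votes.setdefault(v, {}).setdefault(lab, 0)
        votes[v][lab] += 1
    hits = total = 0
    for v, tally in votes.items():
        best = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        total += 1
        hits += int(best in node_labels.labels[v])
    if total == 0:
        raise ValueError("no edges carried predictions")
    return hits / total


Representation = Literal["node", "edge", "iterated"]


def _build_representation(
    G: Digraph, labels: NodeLabeling, representation: Representation,
    inheritance: str = "destination",
) -> tuple[Digraph, NodeLabeling]:
    if representation == "node":
        return G, labels
    p = 1 if representation == "edge" else 2
    L = iterate_line_digraph(G, p) if p > 1 else line_digraph(G)
    return L.graph, inherit_labels(L, labels, mode=inheritance)


def stability_curve(
    G: Digraph,
    labels: NodeLabeling,
    z_grid: Sequence[float],
    representation: Representation = "edge",
    task: str = "classify",
    seed: int = 0,
    cfg: EmbedConfig | None = None,
    inheritance: str = "destination",
) -> list[EvalReport]:
    """Evaluate the pipeline at each sparsification level z of ``z_grid``.

    For each z: sparsify(G, z) → build the representation → NetMF embedding
    → classify (micro/macro F1) or cluster (ARI + modularity).  Each report
    carries the singular gap of the embedded matrix.  Deterministic given
    ``seed``; z = 1 evaluates the unsparsified pipeline.
    """
    cfg = cfg or EmbedConfig()
    reports: list[EvalReport] = []
    for iz, z in enumerate(z_grid):
        if not 0 < z <= 1:
            raise ValueError(f"z values must lie in (0, 1], got {z}")
        try:
            Gz = sparsify(G, z, seed=seed + 1000 * iz) if z < 1 else G
            H, ent_labels = _build_representation(G=Gz, labels=labels,
                                                  representation=representation,
                                                  inheritance=inheritance)
            d = min(cfg.dim, H.n)
            emb = embed_graph(H, replace(cfg, dim=d))
            if task == "classify":
                micro, macro = classify_protocol(emb, ent_labels, seed=seed)
                reports.append(
                    EvalReport(task=task, z=z, micro_f1=micro, macro_f1=macro,
                               singular_gap=emb.singular_gap)
                )
            elif task == "cluster":
                C = ent_labels.class_count
                part = cluster_protocol(emb, C)
                truth = labels_to_partition(ent_labels, emb.basis)
                reports.append(
                    EvalReport(
                        task=task, z=z,
                        ari=adjusted_rand_index(part, truth),
                        modularity_pred=directed_modularity(H, part),
                        modularity_true=directed_modularity(H, truth),
                        singular_gap=emb.singular_gap,
                    )
                )
            else:
                raise ValueError(f"unknown task {task!r}")
        except ValueError as exc:
            raise ValueError(f"stability sweep failed at z = {z}: {exc}") from exc
    return reports
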