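# Methods

This note documents the models and procedures implemented in `ldembed`, the
defaults they use, and the design choices taken where several reasonable
options existed.

## Graph model and conventions

A digraph is simple (no parallel edges; self-loops accepted with a warning,
since they merely induce a line-digraph self-loop), with opaque string node
identifiers.  All linear algebra uses 0-based indices from the stored node
order; the canonical order (nodes sorted by identifier, edges sorted
lexicographically by source/target index) is applied on file input and is
idempotent, so round-trips are byte-stable.  Undirected inputs are
symmetrized by adding both orientations, matching the usual treatment of
undirected benchmarks in digraph pipelines.

Line-digraph nodes are ordered like the parent edges (which reproduces the
lexicographic e1…e9 enumeration of the six-node example) and named by
joining the parent path with `>` (`a>b`, iterates `a>b>c`).  The iteration
ceiling defaults to 2×10⁶ line nodes; exceeding it raises an error that
points the user to the sparsifier rather than attempting the build.

## Incidence orientation and the class factorization

The incidence convention is fixed to A_G = T·Hᵀ and A_ℓG = Hᵀ·T (H marks
heads/targets, T marks tails/sources).  This is the unique orientation
under which the 9×9 product for the worked example comes out entrywise
equal to its known adjacency, and it makes the class factorization exact by
construction: keying equivalence classes by *destination node in canonical
node order* gives Ein = Hᵀ and Eout = T, hence

    A_ℓG = Ein·Eout   and   Eout·Ein = T·Hᵀ = A_G,

so the permutation Q relating class order to node order is the identity.
`ClassFactorization` still carries Q so the invariant Qᵀ·Eout·Ein·Q = A_G
is asserted in its general form; a non-trivial Q would only arise from an
implementation that orders classes by first-seen prototype edges.  The
probability analog EoutP has EoutP[j, f] = T[j, f]·w_f/dout(j), with rows
of out-degree-0 nodes zero.

The factorization identities hold for every digraph; the *rank* statement
rank(A_ℓG) = n additionally requires strong connectivity, so operations
that lean on it warn — but do not fail — when sinks or sources are present
(the rank identity does hold on the toy example, which is sink- and
source-free without being strongly connected).

`exact_rank` uses exact rational elimination (sympy) so the rank claim is
certified rather than thresholded; a floating SVD rank with tolerance
1e-10·σ₁ is provided for large sparse cases and must agree with the exact
path on every test instance.

## Walk operators and diagnostics

Transition matrices are P = D⁻¹A with out-degree (strength) normalization.
Sink rows are left identically zero — substochastic — rather than patched
with teleportation; no operation silently alters the operator.  Trace
comparisons use dense matrix powers up to 2,000 nodes and a seeded
Hutchinson estimator (64 Rademacher probes by default) above that;
the test suite exercises only the dense path.  Non-zero adjacency spectra
are compared by greedy pairing within 1e-6 absolute tolerance after
magnitude sorting.

The linearity identity P_ℓGʳ = Ein·P̄^(r−1)·EoutP is implemented both as a
single-entry evaluation (`edge_similarity_entry`, the Σ_k α_ik form) and as
a whole-matrix residual check (`linearity_check`), which also counts
distinct rows of P_ℓGʳ (≤ n, comparing rows within 1e-9).

HITS is the standard mutually reinforcing power iteration with L2
normalization, tolerance 1e-10, 1000 iterations, flagging rather than
raising on non-convergence.  Note the top singular subspace of a line
digraph is often degenerate (many edges share linkage patterns); the
iteration then converges to the projection of its uniform start onto that
subspace, which is what the eigen-oracle in the tests computes.

Moore-type order bounds use (λ₁^(D+1)−1)/(λ₁−1) with exponent D+2 for the
line digraph; at λ₁ = 1 the geometric-sum limit (D+1, resp. D+2) is
returned.

## Embedding

The similarity matrix is M = (vol(G)/b)·(1/T)·Σ_{r=1..T} Pʳ·D⁻¹ with
window T = 10, negative-sampling parameter b = 1 and dimension d = 128 by
default (d is truncated to the matrix size with a warning).  The NetMF
derivation assumes undirected graphs; for digraphs we use the out-degree
operator and a plain (non-symmetrized) SVD of M̂ = log(max(M, 1)) —
natural log, clip at exactly 1 so M̂ ≥ 0 — reading embeddings from the
left factor U_d·√Σ_d and exposing V_d·√Σ_d as context vectors.  This is
the asymmetric-role treatment familiar from HOPE, and the symmetric √Σ
split is the standard NetMF convention.  The singular gap σ₁ − σ₂ of M̂ is
reported with every embedding; across a sparsification sweep the per-level
gaps are reported as arithmetic means.

Pre-log, S_ℓG = (1/T)ΣP_ℓGʳD⁻¹ has at most n distinct rows and edges
sharing a destination node have *identical* rows — the rank-preservation
property is asserted exactly there.  After the log-clip and truncation the
property survives approximately, which is precisely why destination-label
edge classification works.

Katz similarity K = Σ_{r≤T} βʳAʳ (β = 0.1 default) is provided in a direct
and a factorized line-digraph form (A_ℓGʳ = Ein·A^(r−1)·Eout); the
convergence condition β·λ₁ < 1 is checked against the spectral radius.

The factorized per-entry similarity of ℓG divides by the out-degree of the
*column* line-node: the D⁻¹ factor of the NetMF matrix acts on columns, and
agreement with `netmf_similarity` applied directly to ℓG is the defining
requirement (verified to 1e-10 in the tests).

Occupancy histograms launch 10 walks of length 80 per node (the standard
benchmark walk budget), truncate at sinks, and count occurrences at steps
1..L only — counting starts would make the never-visited fraction
identically zero and destroy the long-tail diagnostic.  Entropy is Shannon
entropy of the visit distribution normalized by log(n).

## Sparsifier

Edge e = (i, j) gets p_e = (1/2n)·(1/dout(i) + 1/din(j)) with unweighted
degrees; on sink/source-free graphs Σp_e = 1 exactly.  The sample-size
bound k = ceil(128·(2n/ε²)·ln(2n/p)) uses the natural logarithm (the
source concentration bound is stated in nats).  Sampling keeps exactly
round(z·m) distinct edges via exponential keys (weighted reservoir), does
*not* reweight survivors (downstream graphs are treated as unweighted, and
the sweep experiments require exact edge fractions), keeps the full node
set so embeddings stay index-aligned across a sweep, and does not enforce
connectivity.

## Evaluation protocols

Classification: stratified seeded 50/50 split; one-vs-rest logistic
regression with L2 regularization, strength C = 1.0, 500 iterations
(fixed, since the upstream protocol defers to framework defaults);
micro/macro F1 on the held-out half.  Multi-label entities are scored by
predicting as many labels as they truly carry, ranked by decision score —
the common node2vec-benchmark rule.  Whether the reference protocol
stratifies its split is unstated; we stratify, and a class missing from
the training half raises with a hint to change the seed.

Clustering: Ward-linkage agglomerative clustering on Euclidean distances,
cut at C = number of label classes (other linkages are an option).  ARI is
the standard permutation-model index (scikit-learn), cross-checked in the
tests against a brute-force pair-counting oracle.  Directed modularity

    Q = (1/W)·Σ_C Σ_{i,j∈C} [A_ij − dout(i)·din(j)/W],   W = Σ_ij A_ij,

is computed by community-wise block sums (equivalent to the naive double
sum, tested to 1e-12); the ground-truth partition's modularity uses the
same code path.  Q = 0 exactly for the single-community partition.

Edge-level predictions can be folded back to nodes by majority vote over
each node's in-edges (`node_proxy_f1`, reported, not thresholded).

Label inheritance defaults to the destination node (an edge is "about"
what it points to); source-mode is available, and for iterates the rule
applies to the terminal (resp. initial) node of the parent path — the
natural recursive extension, configurable because other domains may prefer
origins.

## Synthetic benchmark and what it does (not) show

The directed SBM defaults — two blocks of 20 nodes, p_in = 0.3,
p_out = 0.02, sink/source repair on — produce strongly assortative
two-community digraphs of ≈ 240 edges, the regime in which destination
labels are a clean proxy for community membership.  Repair adds edges
along a random block-respecting Hamiltonian cycle (one edge fixes a sink
and a source simultaneously and cannot create new ones), keeping expected
densities analyzable; the repair count is surfaced in the sample metadata.
`strongly_connected_random` (random Hamiltonian cycle + extra arcs) covers
the strongly connected regime of the rank machinery.

These generators emulate community structure and directionality but not
power-law degree tails, attribute correlations, or the sink/source-heavy
topology of real citation networks — on such graphs line-digraph walks
cannot reach many more distinct contexts and the edge representation's
advantage shrinks.  Passing the synthetic end-to-end checks therefore
demonstrates correctness of the machinery and the expected behavior in the
assortative regime, not performance claims on any particular real dataset.

Problem sizes in the test suite (graphs of ≤ 40 nodes, line digraphs of a
few hundred, 10-seed replications, 10⁴ Monte-Carlo draws for the sampler)
were chosen so every statistical check has conventional 3σ resolution
while the whole suite runs in seconds.

## Numerical tolerances

Exact integer identities (incidence products, factorization, rank) are
asserted with zero tolerance; probabilistic identities at 1e-12 (single
power) to 1e-10 (accumulated powers, r ≤ 10); eigen-comparisons at 1e-6;
Monte-Carlo assertions at 3σ of the corresponding binomial.  All
randomness (walks, sampling, generators, splits) flows from explicit seeds;
no global RNG state is used anywhere.

## Command-line interface

The CLI is a thin layer over the library: `generate`, `linegraph`,
`diagnose`, `embed`, `sparsify`, `classify`, `cluster`, `sweep`.  Reports
are CSV with one row per sparsification level and carry a 12-hex config
digest so any artifact names the exact configuration that produced it.
Defaults mirror the benchmark setup (T = 10, d = 128, β = 0.1, 10×80
walks, representation = line digraph with destination labels).
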