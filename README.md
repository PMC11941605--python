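# ldembed — edge-centric embeddings of directed graphs via line digraphs

`ldembed` is a toolkit for embedding the *edges* of a directed graph instead
of its nodes, aimed at directed biological and information networks
(protein interaction, gene regulation, citation) where the role of a link —
intra-community vs. bridging, hub-to-authority — is the object of interest.

## The idea

Given a digraph G = (V, E) with n nodes and m edges, its **line digraph**
ℓG has one node per edge of G and an arc e → f whenever the head of e is
the tail of f.  With H and T the n×m head/tail incidence matrices,

```
A_G = T·Hᵀ,        A_ℓG = Hᵀ·T.
```

Three structural facts make ℓG a good embedding substrate:

* **Rank property.**  Any two rows of A_ℓG are identical or orthogonal;
  edges sharing a destination node link onwards identically.  Grouping
  edges by destination factorizes A_ℓG = Ein·Eout (Ein an m×n indicator,
  Eout the n distinct rows), and for strongly connected G,
  rank(A_ℓG) = n.
* **Linearity.**  The transition matrices satisfy
  P_ℓGʳ = Ein·P̄^(r−1)·EoutP: every r-step edge-to-edge walk probability is
  a linear combination of n node-to-node (r−1)-step probabilities, so edge
  similarity is a linear function of node similarity and the similarity
  matrix of ℓG keeps ≈ n informative directions however large m is.
* **Quasi-maximum entropy.**  A_G and A_ℓG share their non-zero spectrum
  (a Flanders pair), hence tr(P_ℓGʳ) = tr(P_Gʳ) for all r and
  n·E_G(r) = m·E_ℓG(r) for the expected return probabilities
  E(r) = tr(Pʳ)/size.  Since m ≥ n, walks on ℓG return less often and
  sample the graph more uniformly, mitigating the long-tail effect.

Embeddings are NetMF-style: factorize M̂ = log(max(M, 1)) where
M = (vol/b)·(1/T)·Σ_{r≤T} Pʳ D⁻¹, taking U_d·√Σ_d from the truncated SVD.
Because a directed edge inherits the label of its destination node, edge
classification/clustering on ℓG doubles as a proxy for node classification
— typically a better-conditioned one, by the rank property.

Line digraphs grow fast (up to O(n²) nodes), so large inputs are first
**sparsified** by keeping round(z·m) edges sampled with the
degree-balanced probabilities p_e = (1/2n)·(1/dout(i) + 1/din(j)) for
e = (i, j), which protect edges incident to low-degree endpoints and hence
preserve hubs and authorities; k ≥ 128·(2n/ε²)·ln(2n/p) samples guarantee
spectral error below ε with probability p.

## Worked example

Generate a two-community directed stochastic block model, then sweep the
sparsification level while classifying edges of the line digraph with
destination-inherited labels:

```
$ ldembed generate --blocks 20,20 --p-in 0.3 --p-out 0.02 --seed 0 --out sbm
n=40 m=241 repairs=0
$ ldembed sweep sbm.edges.tsv --labels sbm.labels.tsv --level 1 \
      --seed 0 --z-grid 1.0,0.6,0.4 --out sweep
[ldembed d8b287aebdb1] graph: n=40 m=241
[ldembed d8b287aebdb1] line digraph: 241 nodes, 1485 edges
z=1 micro-F1=1.0000 gap=41.39
z=0.6 micro-F1=0.9589 gap=23.88
z=0.4 micro-F1=0.9792 gap=31.65
```

Reading the output: the 40-node graph has 241 edges, so ℓG has 241 nodes;
the logistic-regression micro-F1 on held-out edges is perfect on the full
graph and stays within 0.05 even after discarding 60% of the edges — the
stability the hub/authority-preserving sampler is designed for.  `gap` is
the singular gap σ₁ − σ₂ of the embedded matrix, a conditioning diagnostic
that correlates with that stability.

The six-node example from the library documentation is built in:

```python
>>> from ldembed import toy_digraph, line_digraph, exact_rank
>>> L = line_digraph(toy_digraph())
>>> L.graph.n, L.graph.m
(9, 12)
>>> exact_rank(L.graph.adjacency(dense=True).astype(int))
6
```

Other subcommands: `linegraph` (build ℓG or ℓᵖG), `diagnose` (trace /
return-probability report for the (G, ℓG) pair), `embed`, `sparsify`,
`classify`, `cluster`.  See `ldembed <cmd> --help`.

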