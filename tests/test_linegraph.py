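import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from ldembed.graph_core import Digraph, NodeLabeling, canonical_order, toy_labels
from ldembed.linegraph import (
    class_factorization,
    exact_rank,
    float_rank,
    incidence_matrices,
    inherit_labels,
    iterate_line_digraph,
    line_digraph,
)
from ldembed.synthetic import strongly_connected_random
from conftest import TOY_LINE_ADJACENCY, random_digraph


def directed_cycle(n: int) -> Digraph:
    nodes = tuple(f"c{i}" for i in range(n))
    return Digraph(nodes, tuple((nodes[i], nodes[(i + 1) % n]) for i in range(n)))


class TestIncidence:
    def test_columns_are_indicators(self, toy):
        pair = incidence_matrices(toy)
        assert (pair.H.sum(axis=0) == 1).all()
        assert (pair.T.sum(axis=0) == 1).all()
        # row of Hᵀ for e1=(a,b) marks the target node b
        assert pair.H.toarray()[toy.node_index["b"], 0] == 1

    def test_reconstruction_identities(self, toy):
        pair = incidence_matrices(toy)
        A = toy.adjacency(dense=True)
        np.testing.assert_array_equal((pair.T @ pair.H.T).toarray(), A)
        np.testing.assert_array_equal(
            (pair.H.T @ pair.T).toarray(), TOY_LINE_ADJACENCY
        )

    def test_single_edge(self):
        G = Digraph(("u", "v"), (("u", "v"),))
        pair = incidence_matrices(G)
        assert pair.H.toarray()[:, 0].tolist() == [0, 1]
        assert pair.T.toarray()[:, 0].tolist() == [1, 0]


class TestLineDigraph:
    def test_toy_matches_printed_adjacency(self, toy):
        L = line_digraph(toy)
        assert L.graph.n == 9 and L.graph.m == 12
        np.testing.assert_array_equal(
            L.graph.adjacency(dense=True).astype(int), TOY_LINE_ADJACENCY
        )

    def test_cycle_is_fixed_point(self):
        L = line_digraph(directed_cycle(3)).graph
        assert L.n == 3 and L.m == 3
        # a 3-cycle again: every node has in/out degree 1 and A³ = I
        A = L.adjacency(dense=True)
        np.testing.assert_array_equal(np.linalg.matrix_power(A, 3), np.eye(3))

    def test_out_star_has_no_line_edges(self):
        G = Digraph(("a", "b", "c"), (("a", "b"), ("a", "c")))
        L = line_digraph(G).graph
        assert L.n == 2 and L.m == 0

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            line_digraph(Digraph(("u",), ()))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_networkx_oracle(self, seed):
        G = random_digraph(seed)
        L = line_digraph(G)
        ours = {(L.parent_map[u], L.parent_map[v]) for u, v in L.graph.edges}
        nxg = nx.DiGraph(list(G.edges))
        theirs = set(nx.line_graph(nxg).edges())
        assert ours == theirs

    @pytest.mark.parametrize("seed", range(8))
    def test_bookkeeping_counts(self, seed):
        # |V(ℓG)| = m and |E(ℓG)| = Σ_j dout(j)·din(j)
        G = random_digraph(seed)
        L = line_digraph(G).graph
        assert L.n == G.m
        assert L.m == int((G.out_degrees() * G.in_degrees()).sum())
        brute = sum(
            1 for (u, v) in G.edges for (x, y) in G.edges if v == x
        )
        assert L.m == brute

    def test_commutes_with_isomorphism(self):
        G = random_digraph(3)
        relabel = {u: f"z{i}" for i, u in enumerate(reversed(G.nodes))}
        H = canonical_order(
            Digraph(
                tuple(relabel[u] for u in G.nodes),
                tuple((relabel[u], relabel[v]) for u, v in G.edges),
            )
        )
        LG = line_digraph(G)
        LH = line_digraph(H)
        ours = {
            (relabel[p[0]], relabel[p[1]], relabel[q[0]], relabel[q[1]])
            for (u, v) in LG.graph.edges
            for p, q in [(LG.parent_map[u], LG.parent_map[v])]
        }
        theirs = {
            (p[0], p[1], q[0], q[1])
            for (u, v) in LH.graph.edges
            for p, q in [(LH.parent_map[u], LH.parent_map[v])]
        }
        assert ours == theirs


class TestIterated:
    def test_toy_second_iterate_has_12_nodes(self, toy):
        L2 = iterate_line_digraph(toy, 2)
        assert L2.graph.n == 12
        assert L2.level == 2
        # nodes are directed length-2 paths of G
        assert all(len(p) == 3 for p in L2.parent_map.values())

    def test_second_iterate_edges_are_length2_paths_of_lg(self, toy):
        L = line_digraph(toy).graph
        L2 = iterate_line_digraph(toy, 2)
        brute = sum(1 for (u, v) in L.edges for (x, y) in L.edges if v == x)
        assert L2.graph.m == brute

    def test_level_one_equals_line_digraph(self, toy):
        assert iterate_line_digraph(toy, 1).graph == line_digraph(toy).graph

    def test_ceiling_advises_sparsification(self, toy):
        with pytest.raises(ValueError, match="sparsify"):
            iterate_line_digraph(toy, 3, node_ceiling=5)


class TestInheritLabels:
    def test_destination_mode(self, toy, toy_two_communities):
        L = line_digraph(toy)
        lab = inherit_labels(L, toy_two_communities, mode="destination")
        assert lab.labels["c>d"] == frozenset({"green"})

    def test_source_mode(self, toy, toy_two_communities):
        L = line_digraph(toy)
        lab = inherit_labels(L, toy_two_communities, mode="source")
        assert lab.labels["c>d"] == frozenset({"blue"})

    def test_uniform_labels_propagate(self, toy):
        uniform = NodeLabeling.from_single({u: "only" for u in toy.nodes})
        lab = inherit_labels(line_digraph(toy), uniform)
        assert all(v == frozenset({"only"}) for v in lab.labels.values())

    def test_iterated_inheritance_uses_terminal_node(self, toy, toy_two_communities):
        L2 = iterate_line_digraph(toy, 2)
        lab = inherit_labels(L2, toy_two_communities)
        for name, path in L2.parent_map.items():
            assert lab.labels[name] == toy_two_communities.labels[path[-1]]

    def test_unlabeled_node_listed(self, toy):
        partial = NodeLabeling.from_single({"a": "x"})
        with pytest.raises(ValueError, match="unlabeled"):
            inherit_labels(line_digraph(toy), partial)


class TestClassFactorization:
    def test_toy_reproduces_printed_matrix(self, toy):
        cf = class_factorization(toy)  # toy has neither sinks nor sources
        assert cf.Eout.shape == (6, 9)
        np.testing.assert_array_equal(cf.Ein @ cf.Eout, TOY_LINE_ADJACENCY)
        np.testing.assert_array_equal(
            cf.Q.T @ cf.Eout @ cf.Ein @ cf.Q, toy.adjacency(dense=True).astype(int)
        )
        # six distinct rows in the printed 9×9 matrix
        assert len({tuple(r) for r in TOY_LINE_ADJACENCY}) == 6

    def test_classes_group_by_destination(self, toy):
        cf = class_factorization(toy)
        for k, (_, v) in enumerate(toy.edges):
            assert cf.Ein[k].argmax() == toy.node_index[v]
            assert cf.Ein[k].sum() == 1

    def test_cycle_is_all_singletons(self):
        G = directed_cycle(5)
        cf = class_factorization(G)
        # Ein a permutation, Eout = A_ℓG
        assert (cf.Ein.sum(axis=0) == 1).all() and (cf.Ein.sum(axis=1) == 1).all()
        A_l = line_digraph(G).graph.adjacency(dense=True).astype(int)
        np.testing.assert_array_equal(cf.Ein @ cf.Eout, A_l)
        np.testing.assert_array_equal(cf.Eout, cf.Ein.T @ A_l)

    @pytest.mark.parametrize("seed", range(8))
    def test_identities_on_random_graphs(self, seed):
        G = random_digraph(seed)
        with pytest.warns() if _has_sink_or_source(G) else _nullcontext():
            cf = class_factorization(G)
        A_l = line_digraph(G).graph.adjacency(dense=True).astype(int)
        np.testing.assert_array_equal(cf.Ein @ cf.Eout, A_l)
        np.testing.assert_array_equal(
            cf.Q.T @ cf.Eout @ cf.Ein @ cf.Q, G.adjacency(dense=True).astype(int)
        )


def _has_sink_or_source(G):
    return (G.out_degrees() == 0).any() or (G.in_degrees() == 0).any()


from contextlib import nullcontext as _nullcontext


class TestRank:
    def test_toy_line_adjacency_rank_is_node_count(self):
        # frozen from independent rational row reduction of the 9×9 matrix
        assert exact_rank(TOY_LINE_ADJACENCY) == 6

    def test_degenerate_cases(self):
        assert exact_rank(np.zeros((4, 4), dtype=int)) == 0
        assert exact_rank(np.eye(5, dtype=int)) == 5

    @pytest.mark.parametrize("seed", range(10))
    def test_rank_equals_n_for_strongly_connected(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        G = strongly_connected_random(n, int(rng.integers(0, n)), seed)
        assert _brute_force_strongly_connected(G)
        A_l = line_digraph(G).graph.adjacency(dense=True).astype(int)
        assert exact_rank(A_l) == n
        assert float_rank(A_l) == n  # the float path must agree

    @pytest.mark.parametrize("seed", range(8))
    def test_rows_orthogonal_or_identical(self, seed):
        A = line_digraph(random_digraph(seed)).graph.adjacency(dense=True)
        m = A.shape[0]
        for i in range(m):
            for j in range(i + 1, m):
                identical = (A[i] == A[j]).all()
                orthogonal = float(A[i] @ A[j]) == 0.0
                assert identical or orthogonal


def _brute_force_strongly_connected(G) -> bool:
    A = G.adjacency(dense=True) > 0
    reach = np.eye(G.n, dtype=bool) | A
    for _ in range(G.n):
        reach = reach | (reach @ A)
    return bool(reach.all())
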