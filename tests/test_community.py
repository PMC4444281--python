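"""Modularity, Louvain detection vs exhaustive search, partition comparison,
and coarse-grained community structure."""

import itertools

import networkx as nx
import numpy as np
import pytest

from coexnet import (
    coarse_grain,
    community_letters,
    compare_partitions,
    detect_communities,
    generate_planted_partition_graph,
    modularity,
    top_communities,
)
from tests.conftest import random_connected_graph


def set_partitions(items):
    """All partitions of a list into non-empty blocks (restricted growth)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def best_partition_bruteforce(g):
    best_q, best_p = -np.inf, None
    for blocks in set_partitions(list(g.nodes())):
        assignment = {v: i for i, block in enumerate(blocks) for v in block}
        q = modularity(g, assignment)
        if q > best_q:
            best_q, best_p = q, assignment
    return best_q, best_p


class TestModularity:
    def test_two_disjoint_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        part = {v: (0 if v < 3 else 1) for v in g.nodes()}
        assert modularity(g, part) == pytest.approx(0.5)

    def test_single_community_is_zero(self):
        g = nx.gnp_random_graph(20, 0.2, seed=1)
        assert modularity(g, {v: 0 for v in g}) == pytest.approx(0.0)

    def test_singletons_formula(self):
        g = nx.gnp_random_graph(15, 0.3, seed=2)
        L = g.number_of_edges()
        expected = -sum((d / (2 * L)) ** 2 for _, d in g.degree())
        assert modularity(g, {v: v for v in g}) == pytest.approx(expected)

    def test_matches_networkx_on_random_partitions(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            g = random_connected_graph(25, 0.15, rng)
            part = {v: int(rng.integers(0, 4)) for v in g.nodes()}
            comms = {}
            for v, c in part.items():
                comms.setdefault(c, set()).add(v)
            q_nx = nx.community.modularity(g, comms.values())
            assert modularity(g, part) == pytest.approx(q_nx, abs=1e-12)

    def test_bounds_on_arbitrary_partitions(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_connected_graph(20, 0.2, rng)
            part = {v: int(rng.integers(0, 5)) for v in g.nodes()}
            assert -0.5 <= modularity(g, part) <= 1.0

    def test_edgeless_graph_is_zero_with_warning(self, caplog):
        g = nx.empty_graph(3)
        assert modularity(g, {v: 0 for v in g}) == 0.0

    def test_incomplete_assignment_rejected(self):
        g = nx.path_graph(4)
        with pytest.raises(ValueError, match="misses"):
            modularity(g, {0: 0, 1: 0})


class TestDetectCommunities:
    def test_two_cliques_with_bridge(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 6)
        part = detect_communities(g, seed=1)
        assert part.n_communities == 2
        blocks = part.members()
        assert {frozenset(b) for b in blocks} == {
            frozenset(range(6)), frozenset(range(6, 12))
        }
        assert part.q == pytest.approx(modularity(g, part.community_of_node), abs=1e-12)

    def test_complete_graph_stays_whole(self):
        part = detect_communities(nx.complete_graph(6), seed=0)
        assert part.n_communities == 1 and part.q == pytest.approx(0.0)

    def test_attains_bruteforce_optimum_on_small_graphs(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            g = random_connected_graph(7, 0.4, rng)
            q_star, _ = best_partition_bruteforce(g)
            part = detect_communities(g, seed=int(rng.integers(2**31)), n_restarts=10)
            assert part.q <= q_star + 1e-12
            assert part.q == pytest.approx(q_star, abs=1e-9)

    def test_seed_determinism(self):
        g = nx.gnp_random_graph(60, 0.08, seed=12)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        p1 = detect_communities(g, seed=5, n_restarts=4)
        p2 = detect_communities(g, seed=5, n_restarts=4)
        assert p1.community_of_node == p2.community_of_node and p1.q == p2.q

    def test_single_node(self):
        g = nx.empty_graph(1)
        part = detect_communities(g, seed=0)
        assert part.n_communities == 1 and part.q == 0.0

    def test_planted_partition_recovery(self):
        g, truth = generate_planted_partition_graph(200, 4, 0.5, 0.01, seed=7)
        part = detect_communities(g, seed=3)
        _, nmi = compare_partitions(part.community_of_node, truth.community_of_node)
        assert nmi >= 0.9

    def test_labels_contiguous_and_size_ordered(self):
        g, _ = generate_planted_partition_graph(90, 3, 0.5, 0.02, seed=4)
        part = detect_communities(g, seed=1)
        sizes = [len(b) for b in part.members()]
        assert sorted(set(part.community_of_node.values())) == list(range(part.n_communities))
        assert sizes == sorted(sizes, reverse=True)


class TestComparePartitions:
    def test_label_permutation_is_identical(self):
        a = {v: v % 3 for v in range(30)}
        b = {v: (v % 3 + 1) % 3 for v in range(30)}
        assert compare_partitions(a, b) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_all_in_one_vs_singletons(self):
        a = {v: 0 for v in range(10)}
        b = {v: v for v in range(10)}
        ari, _ = compare_partitions(a, b)
        assert ari == pytest.approx(0.0)

    def test_hand_contingency_example(self):
        """Contingency ((2,1),(1,2)) on 6 items: ARI = -1/9 by the closed form."""
        a = {i: l for i, l in enumerate([0, 0, 0, 1, 1, 1])}
        b = {i: l for i, l in enumerate([0, 0, 1, 0, 1, 1])}
        ari, _ = compare_partitions(a, b)
        assert ari == pytest.approx(-1 / 9)

    def test_node_mismatch_errors(self):
        with pytest.raises(ValueError, match="different nodes"):
            compare_partitions({1: 0, 2: 0}, {2: 0, 3: 0})


class TestCoarseGrain:
    def test_two_triangles_and_bridge(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        g.add_edge(0, 3)
        part = {v: (0 if v < 3 else 1) for v in g.nodes()}
        coarse = coarse_grain(g, part)
        assert coarse.intra_edges == {0: 3, 1: 3}
        assert coarse.inter_edges == {frozenset((0, 1)): 1}
        assert coarse.weight_fraction[frozenset((0, 1))] == pytest.approx(1 / 7)
        assert coarse.sizes == {0: 3, 1: 3}

    def test_single_community(self):
        g = nx.complete_graph(4)
        coarse = coarse_grain(g, {v: 0 for v in g})
        assert coarse.inter_edges == {} and coarse.intra_edges == {0: 6}

    def test_edge_conservation_random(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            g = nx.gnp_random_graph(30, 0.15, seed=int(rng.integers(2**31)))
            part = {v: int(rng.integers(0, 5)) for v in g.nodes()}
            coarse = coarse_grain(g, part)
            total = sum(coarse.intra_edges.values()) + sum(coarse.inter_edges.values())
            assert total == g.number_of_edges()
            assert sum(coarse.sizes.values()) == g.number_of_nodes()

    def test_mixing_matrix_graph_view(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        g.add_edge(0, 3)
        coarse = coarse_grain(g, {v: (0 if v < 3 else 1) for v in g.nodes()})
        cg = coarse.to_graph()
        assert cg.nodes[0]["size"] == 3 and cg[0][1]["weight"] == 1


class TestTopCommunities:
    @pytest.fixture()
    def coarse(self):
        g = nx.Graph()
        comms = {0: 10, 1: 5, 2: 2}
        part = {}
        node = 0
        for c, size in comms.items():
            members = list(range(node, node + size))
            node += size
            for u, v in itertools.combinations(members, 2):
                g.add_edge(u, v)
            part.update({m: c for m in members})
        g.add_edge(0, 10)
        g.add_edge(10, 15)
        return coarse_grain(g, part)

    def test_keeps_largest_k(self, coarse):
        top = top_communities(coarse, 2)
        assert set(top.sizes) == {0, 1}
        assert top.inter_edges == {frozenset((0, 1)): 1}
        assert top.total_edges == coarse.total_edges  # fractions stay global

    def test_keep_list_union(self, coarse):
        top = top_communities(coarse, 1, keep={2})
        assert set(top.sizes) == {0, 2}

    def test_k_larger_than_available_returns_all(self, coarse):
        top = top_communities(coarse, 99)
        assert set(top.sizes) == {0, 1, 2}

    def test_identity_on_single_community(self):
        g = nx.complete_graph(3)
        coarse = coarse_grain(g, {v: 0 for v in g})
        assert top_communities(coarse, 1).sizes == coarse.sizes


def test_community_letters():
    letters = community_letters(30)
    assert letters[:3] == ["A", "B", "C"]
    assert letters[25] == "Z" and letters[26] == "AA" and letters[27] == "AB"
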