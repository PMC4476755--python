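import itertools

import numpy as np
import pytest

from trianet.communities import (CommunityAssignment, connected_components,
                                 louvain, modularity)
from trianet.triad_graph import TriadGraph

from conftest import oracle_components, random_similarity


def graph_from_edges(n, edges, weighted=False, multiplicity=None):
    edges = np.asarray(sorted(tuple(sorted(e)) for e in set(map(tuple, edges))),
                       dtype=np.int64).reshape(-1, 2)
    mult = np.asarray(multiplicity if multiplicity is not None
                      else np.ones(len(edges)), dtype=np.int64)
    return TriadGraph([f"S{i}" for i in range(n)], edges, mult, [], weighted=weighted)


def triangle(offset=0):
    return [(offset, offset + 1), (offset + 1, offset + 2), (offset, offset + 2)]


def two_triangles():
    return graph_from_edges(6, triangle(0) + triangle(3))


def assignment(g, labels):
    return CommunityAssignment(g.samples, np.asarray(labels), None, "manual")


def best_partition_q(g):
    """Exhaustive modularity maximum over all partitions (small n only)."""
    n = g.n
    best = -np.inf
    labels = np.zeros(n, dtype=int)

    def rec(v, k):
        nonlocal best
        if v == n:
            best = max(best, modularity(g, CommunityAssignment(
                g.samples, labels.copy(), None, "enum")))
            return
        for c in range(k + 1):
            labels[v] = c
            rec(v + 1, max(k, c + 1))

    labels[0] = 0
    rec(1, 1)
    return best


class TestConnectedComponents:
    def test_two_disjoint_triangles(self):
        a = connected_components(two_triangles())
        assert a.n_communities == 2
        assert list(a.sizes()) == [3, 3]
        assert list(a.membership) == [0, 0, 0, 1, 1, 1]

    def test_connected_graph_is_one_component(self):
        g = graph_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        assert connected_components(g).n_communities == 1

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 21))
            m = int(rng.integers(2, 2 * n))
            edges = {tuple(sorted(rng.choice(n, 2, replace=False))) for _ in range(m)}
            g = graph_from_edges(n, list(edges))
            ours = connected_components(g).membership
            expect = oracle_components(n, edges)
            assert np.array_equal(ours, expect)

    def test_labels_ordered_by_smallest_vertex(self):
        g = graph_from_edges(6, [(3, 4), (0, 5), (1, 2)])
        a = connected_components(g)
        # component of vertex 0 gets label 0, of vertex 1 label 1, ...
        assert a.membership[0] == 0 and a.membership[1] == 1 and a.membership[3] == 2


class TestModularity:
    def test_single_community_is_zero(self, rng):
        d = random_similarity(10, rng)
        from trianet.triad_graph import build_triad_graph
        g = build_triad_graph(d)
        assert modularity(g, assignment(g, np.zeros(10, dtype=int))) == pytest.approx(0.0)

    def test_two_disjoint_triangles_is_half(self):
        g = two_triangles()
        q = modularity(g, assignment(g, [0, 0, 0, 1, 1, 1]))
        assert q == pytest.approx(0.5)

    def test_triangle_singletons(self):
        g = graph_from_edges(3, triangle())
        q = modularity(g, assignment(g, [0, 1, 2]))
        assert q == pytest.approx(-1.0 / 3.0)

    def test_invariant_under_relabeling(self, rng):
        g = two_triangles()
        labels = np.array([0, 1, 0, 1, 2, 2])
        q0 = modularity(g, assignment(g, labels))
        perm = rng.permutation(3)
        q1 = modularity(g, assignment(g, perm[labels]))
        assert q0 == pytest.approx(q1)

    def test_matches_igraph_on_random_partitions(self, rng):
        import igraph as ig
        for _ in range(10):
            n = int(rng.integers(5, 15))
            edges = {tuple(sorted(rng.choice(n, 2, replace=False)))
                     for _ in range(2 * n)}
            g = graph_from_edges(n, list(edges))
            from trianet.communities import _canonical_labels
            labels = _canonical_labels(rng.integers(0, 3, size=n))
            q = modularity(g, assignment(g, labels))
            gg = ig.Graph(n=n, edges=[tuple(e) for e in g.edges])
            assert q == pytest.approx(gg.modularity(list(labels)), abs=1e-12)

    def test_zero_edges_error(self):
        g = TriadGraph(["a", "b"], np.empty((0, 2), dtype=np.int64),
                       np.empty(0, dtype=np.int64), [])
        with pytest.raises(ValueError, match="undefined"):
            modularity(g, assignment(g, [0, 1]))


class TestLouvain:
    def test_two_triangles_recovered_at_optimum(self):
        g = two_triangles()
        a = louvain(g)
        assert list(a.membership) == [0, 0, 0, 1, 1, 1]
        assert a.modularity == pytest.approx(0.5)
        assert a.modularity == pytest.approx(best_partition_q(g))

    def test_single_triangle_stays_together(self):
        g = graph_from_edges(3, triangle())
        a = louvain(g)
        assert a.n_communities == 1
        assert a.modularity == pytest.approx(0.0)

    def test_four_disjoint_cliques(self):
        edges = []
        for b in range(4):
            edges += list(itertools.combinations(range(5 * b, 5 * b + 5), 2))
        g = graph_from_edges(20, edges)
        a = louvain(g)
        assert a.n_communities == 4
        # 4 equal disjoint cliques: e = diag(1/4), Q = 4 (1/4 - 1/16)
        assert a.modularity == pytest.approx(0.75)

    def test_refines_components_and_is_monotone(self, rng):
        from trianet.triad_graph import build_triad_graph
        for seed in range(5):
            d = random_similarity(24, np.random.default_rng(seed))
            g = build_triad_graph(d)
            comps = connected_components(g)
            comm = louvain(g)
            # refinement: one louvain community never spans two components
            for c in range(comm.n_communities):
                assert len(set(comps.membership[comm.membership == c])) == 1
            assert comm.modularity >= modularity(g, comps) - 1e-12

    def test_nonnegative_q_on_disconnected_graph(self, rng):
        g = two_triangles()
        assert louvain(g).modularity >= 0

    def test_deterministic_without_shuffle(self, rng):
        d = random_similarity(30, rng)
        from trianet.triad_graph import build_triad_graph
        g = build_triad_graph(d)
        a1 = louvain(g, seed=1)
        a2 = louvain(g, seed=2)  # seed irrelevant without shuffle
        assert np.array_equal(a1.membership, a2.membership)

    def test_agrees_with_igraph_multilevel_on_planted_structure(self):
        import igraph as ig
        g = two_triangles()
        ours = louvain(g)
        gg = ig.Graph(n=g.n, edges=[tuple(e) for e in g.edges])
        ref = gg.community_multilevel()
        assert ours.n_communities == len(ref)
        assert ours.modularity == pytest.approx(ref.modularity)

    def test_zero_edge_graph_rejected(self):
        g = TriadGraph(["a", "b", "c"], np.empty((0, 2), dtype=np.int64),
                       np.empty(0, dtype=np.int64), [])
        with pytest.raises(ValueError):
            louvain(g)


def test_assignment_export(tmp_path):
    g = two_triangles()
    a = louvain(g)
    p = tmp_path / "comm.tsv"
    a.write(str(p))
    rows = [line.split("\t") for line in p.read_text().strip().split("\n")]
    assert len(rows) == 6 and rows[0][0] == "S0"
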