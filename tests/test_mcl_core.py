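import numpy as np
import pytest
from scipy import sparse

from cypclass.mcl_core import Clustering, MclParams, mcl_step, run_mcl, to_stochastic
from cypclass.simgraph import SimilarityGraph
from conftest import clique_graph, random_graph
from oracles import dense_mcl_partition, dense_mcl_step


def as_partition_of_indices(clustering, nodes):
    index = {n: i for i, n in enumerate(nodes)}
    return {frozenset(index[n] for n in c) for c in clustering.clusters}


def graph_adjacency(graph):
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for n, w in graph.self_loops.items():
        a[index[n], index[n]] = w
    for (x, y), w in graph.edges.items():
        a[index[x], index[y]] = w
        a[index[y], index[x]] = w
    return a, nodes


class TestToStochastic:
    def test_single_node(self):
        g = SimilarityGraph(nodes=["a"], edges={}, self_loops={"a": 1.0})
        m, order = to_stochastic(g)
        assert order == ["a"]
        assert m.toarray() == pytest.approx(np.array([[1.0]]))

    def test_two_node_column_sums(self):
        g = SimilarityGraph(
            nodes=["a", "b"], edges={("a", "b"): 1.0},
            self_loops={"a": 1.0, "b": 1.0},
        )
        m, _ = to_stochastic(g)
        assert np.asarray(m.sum(axis=0)).ravel() == pytest.approx([1.0, 1.0])

    def test_random_graph_column_sums(self):
        g = random_graph(np.random.default_rng(11), 20)
        m, _ = to_stochastic(g)
        sums = np.asarray(m.sum(axis=0)).ravel()
        assert sums == pytest.approx(np.ones(20), abs=1e-12)


class TestMclStep:
    def test_identity_fixed_point(self):
        m = sparse.identity(5, format="csc")
        out = mcl_step(m, inflation=3.0)
        assert (out - m).nnz == 0

    def test_uniform_2x2_fixed_point(self):
        m = sparse.csc_matrix(np.full((2, 2), 0.5))
        out = mcl_step(m, inflation=2.0)
        assert out.toarray() == pytest.approx(np.full((2, 2), 0.5))

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.random((10, 10)) * (rng.random((10, 10)) < 0.5)
            np.fill_diagonal(a, rng.random(10) + 0.1)
            m_dense = a / a.sum(axis=0)
            expected = dense_mcl_step(m_dense, inflation=2.5, prune=1e-5)
            out = mcl_step(sparse.csc_matrix(m_dense), inflation=2.5, prune_threshold=1e-5)
            assert out.toarray() == pytest.approx(expected, abs=1e-10)

    def test_stochasticity_preserved_over_iterations(self):
        g = random_graph(np.random.default_rng(17), 25)
        m, _ = to_stochastic(g)
        for _ in range(12):
            m = mcl_step(m, inflation=2.0)
            sums = np.asarray(m.sum(axis=0)).ravel()
            assert sums == pytest.approx(np.ones(25), abs=1e-9)


class TestRunMcl:
    def test_two_disjoint_triangles(self):
        g = clique_graph([["a", "b", "c"], ["x", "y", "z"]])
        clustering = run_mcl(g, MclParams(inflation=2.0))
        assert {frozenset(c) for c in clustering.clusters} == {
            frozenset({"a", "b", "c"}),
            frozenset({"x", "y", "z"}),
        }

    def test_barbell_splits_at_weak_bridge(self):
        g = clique_graph(
            [["a", "b", "c"], ["x", "y", "z"]],
            bridges=[("c", "x", 0.1)],
        )
        clustering = run_mcl(g, MclParams(inflation=5.0))
        assert {frozenset(c) for c in clustering.clusters} == {
            frozenset({"a", "b", "c"}),
            frozenset({"x", "y", "z"}),
        }

    def test_isolated_node_is_singlet(self):
        g = SimilarityGraph(
            nodes=["a", "b", "lone"],
            edges={("a", "b"): 5.0},
            self_loops={"a": 5.0, "b": 5.0, "lone": 1.0},
        )
        clustering = run_mcl(g)
        assert frozenset({"lone"}) in set(clustering.clusters)

    def test_clusters_never_span_components(self):
        rng = np.random.default_rng(23)
        for trial in range(10):
            sizes = rng.integers(2, 6, size=rng.integers(2, 5))
            cliques, offset = [], 0
            for s in sizes:
                cliques.append([f"c{offset + i}" for i in range(s)])
                offset += s
            g = clique_graph(cliques)
            clustering = run_mcl(g, MclParams(inflation=2.0))
            comp_of = {}
            for i, c in enumerate(cliques):
                for n in c:
                    comp_of[n] = i
            for cluster in clustering.clusters:
                assert len({comp_of[n] for n in cluster}) == 1

    def test_higher_inflation_never_coarser_on_bridged_cliques(self):
        g = clique_graph(
            [["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]],
            bridges=[("a4", "b1", 0.5)],
        )
        n_low = run_mcl(g, MclParams(inflation=1.5)).n_clusters
        n_high = run_mcl(g, MclParams(inflation=5.0)).n_clusters
        assert n_high >= n_low

    @pytest.mark.parametrize("inflation", [1.5, 2.0, 3.0, 5.0])
    def test_agreement_with_dense_reference(self, inflation):
        """Sparse implementation partitions == independent dense MCL on
        random graphs of <= 30 nodes."""
        rng = np.random.default_rng(int(inflation * 10))
        for trial in range(15):
            g = random_graph(rng, int(rng.integers(5, 31)), edge_prob=0.25)
            a, nodes = graph_adjacency(g)
            expected = dense_mcl_partition(a, inflation)
            got = as_partition_of_indices(run_mcl(g, MclParams(inflation=inflation)), nodes)
            assert got == expected

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError, match="inflation"):
            MclParams(inflation=1.0)


class TestClustering:
    def test_partition_validation(self):
        with pytest.raises(ValueError, match="disjoint"):
            Clustering(clusters=[frozenset({"a"}), frozenset({"a", "b"})], n_nodes=2)
        with pytest.raises(ValueError, match="empty"):
            Clustering(clusters=[frozenset()], n_nodes=0)

    def test_labels_deterministic(self):
        c = Clustering(
            clusters=[frozenset({"x"}), frozenset({"a", "b"})], n_nodes=3
        )
        labels = c.labels()
        assert labels["a"] == labels["b"] == 0  # biggest cluster first
        assert labels["x"] == 1
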