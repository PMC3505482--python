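import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cypclass.simgraph import (
    LOG_EVALUE_CAP,
    EdgeFilterParams,
    build_graph,
    filter_hits,
    query_coverage,
    symmetrize,
)
from conftest import make_hit
from oracles import bitmap_coverage


class TestQueryCoverage:
    def test_full_cover(self):
        assert query_coverage([make_hit(qs=1, qe=100)], 100) == 100.0

    def test_overlapping_hsps_merged(self):
        hsps = [make_hit(qs=1, qe=50), make_hit(qs=41, qe=90)]
        assert query_coverage(hsps, 100) == 90.0

    def test_interval_beyond_query_rejected(self):
        with pytest.raises(ValueError, match="exceeds query length"):
            query_coverage([make_hit(qs=50, qe=120)], 100)

    def test_mixed_pairs_rejected(self):
        hsps = [make_hit(q="a", s="b"), make_hit(q="a", s="c")]
        with pytest.raises(ValueError, match="same query and subject"):
            query_coverage(hsps, 100)

    @settings(max_examples=1000, deadline=None)
    @given(
        query_len=st.integers(10, 300),
        data=st.data(),
    )
    def test_matches_bitmap_oracle(self, query_len, data):
        intervals = data.draw(
            st.lists(
                st.tuples(st.integers(1, query_len), st.integers(0, 80)).map(
                    lambda t: (t[0], min(t[0] + t[1], query_len))
                ),
                min_size=1,
                max_size=8,
            )
        )
        hsps = [make_hit(qs=s, qe=e) for s, e in intervals]
        expected = bitmap_coverage(intervals, query_len)
        assert query_coverage(hsps, query_len) == pytest.approx(expected, abs=1e-9)


class TestFilterHits:
    LENGTHS = {"a": 100, "b": 100}

    def test_passing_hit_retained(self):
        hits = [make_hit(evalue=1e-60, qs=1, qe=70)]  # coverage 70%
        assert ("a", "b") in filter_hits(hits, EdgeFilterParams(), self.LENGTHS)

    def test_evalue_boundary_drops(self):
        hits = [make_hit(evalue=1e-40, qs=1, qe=90)]  # coverage 90% but E too high
        assert filter_hits(hits, EdgeFilterParams(), self.LENGTHS) == {}

    def test_coverage_boundary_drops(self):
        lengths = {"a": 1000, "b": 1000}
        hits = [make_hit(evalue=1e-80, qs=1, qe=599)]  # coverage 59.9%
        assert filter_hits(hits, EdgeFilterParams(), lengths) == {}

    def test_self_hits_never_edges(self):
        hits = [make_hit(q="a", s="a", evalue=0.0)]
        assert filter_hits(hits, EdgeFilterParams(), self.LENGTHS) == {}

    def test_best_evalue_over_hsps(self):
        hits = [
            make_hit(evalue=1e-20, qs=1, qe=40),
            make_hit(evalue=1e-60, qs=30, qe=80),
        ]
        retained = filter_hits(hits, EdgeFilterParams(), self.LENGTHS)
        assert retained == {("a", "b"): 1e-60}  # coverage from union [1,80] = 80%

    @settings(max_examples=50, deadline=None)
    @given(
        e1=st.floats(1e-80, 1e-30),
        cov1=st.integers(30, 100),
        tighter_e=st.floats(1e-80, 1e-55),
        higher_cov=st.integers(60, 100),
    )
    def test_filter_monotonicity(self, e1, cov1, tighter_e, higher_cov):
        """Lowering e_max or raising cov_min never adds directed pairs."""
        rng = np.random.default_rng(0)
        lengths = {f"n{i}": 100 for i in range(10)}
        hits = []
        for i in range(9):
            qe = int(rng.integers(30, 101))
            hits.append(
                make_hit(
                    q=f"n{i}", s=f"n{i + 1}",
                    evalue=float(10 ** rng.uniform(-75, -20)), qs=1, qe=qe,
                )
            )
        loose = filter_hits(hits, EdgeFilterParams(e_max=max(e1, tighter_e), cov_min=min(cov1, higher_cov)), lengths)
        tight = filter_hits(hits, EdgeFilterParams(e_max=min(e1, tighter_e), cov_min=max(cov1, higher_cov)), lengths)
        assert set(tight) <= set(loose)


class TestSymmetrize:
    def test_one_direction_is_no_edge(self):
        g = symmetrize({("a", "b"): 1e-60}, ["a", "b"])
        assert g.edges == {}
        assert g.self_loops == {"a": 1.0, "b": 1.0}

    def test_weight_is_mean_of_log_evalues(self):
        g = symmetrize({("a", "b"): 1e-60, ("b", "a"): 1e-80}, ["a", "b"])
        assert g.edges[("a", "b")] == pytest.approx(70.0)

    def test_zero_evalue_capped(self):
        g = symmetrize({("a", "b"): 0.0, ("b", "a"): 0.0}, ["a", "b"])
        assert g.edges[("a", "b")] == LOG_EVALUE_CAP == 200.0

    def test_self_loop_is_max_incident_weight(self):
        directed = {
            ("a", "b"): 1e-60, ("b", "a"): 1e-60,
            ("b", "c"): 1e-100, ("c", "b"): 1e-100,
        }
        g = symmetrize(directed, ["a", "b", "c"])
        assert g.self_loops["b"] == pytest.approx(100.0)
        assert g.self_loops["a"] == pytest.approx(60.0)

    def test_matrix_symmetric_nonneg_positive_diagonal(self):
        rng = np.random.default_rng(3)
        directed = {}
        nodes = [f"n{i}" for i in range(12)]
        for _ in range(30):
            a, b = rng.choice(nodes, size=2, replace=False)
            e = float(10 ** rng.uniform(-90, -51))
            directed[(a, b)] = e
            if rng.random() < 0.7:
                directed[(b, a)] = float(10 ** rng.uniform(-90, -51))
        g = symmetrize(directed, nodes)
        from cypclass.mcl_core import to_stochastic

        for (a, b), w in g.edges.items():
            assert w > 0
        m, order = to_stochastic(g)
        dense = m.toarray()
        assert (dense >= 0).all()
        assert (np.diag(dense) > 0).all()


class TestBuildGraph:
    def test_round_trip_edge_list(self, tmp_path, small_hits, small_proteome):
        records, _ = small_proteome
        lengths = {r.id: len(r) for r in records}
        g = build_graph(small_hits, lengths)
        path = tmp_path / "graph.tsv"
        g.write_edge_list(path, header_lines=["test"])
        from cypclass.simgraph import SimilarityGraph

        back = SimilarityGraph.read_edge_list(path)
        assert set(back.nodes) == set(g.nodes)
        assert back.edges.keys() == g.edges.keys()
        for k in g.edges:
            assert back.edges[k] == pytest.approx(g.edges[k], rel=1e-5)
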