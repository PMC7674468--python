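import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import _oracles as orc
from dicn import (
    auc_exhaustive,
    auc_over_comparisons,
    build_graph,
    filter_equal_common_neighbours,
    filter_no_common_neighbour,
    motivation_stats,
    planted_two_community_graph,
    run_experiment,
    score_pairs,
    split_edges,
    train_probe_example,
    training_graph,
)

FULL_EDGES = [("1", "2"), ("2", "3"), ("2", "5"), ("3", "4"), ("3", "5")]


class TestSplitEdges:
    def test_80_20_of_five_edges(self):
        s = split_edges(FULL_EDGES, beta=80, seed=3)
        assert len(s.training_edges) == 4
        assert len(s.probe_edges) == 1
        assert s.training_edges | s.probe_edges == {
            tuple(sorted(e)) for e in FULL_EDGES
        }
        assert not s.training_edges & s.probe_edges
        assert len(s.non_existing) == 10 - 5

    def test_half_split_rounding(self):
        edges = [(str(i), str(i + 1)) for i in range(10)]
        s = split_edges(edges, beta=50, seed=0)
        assert len(s.training_edges) == 5

    def test_deterministic_and_order_invariant(self):
        a = split_edges(FULL_EDGES, beta=60, seed=11)
        b = split_edges(list(reversed(FULL_EDGES)), beta=60, seed=11)
        assert a == b

    def test_probe_never_empty(self):
        s = split_edges(FULL_EDGES, beta=99, seed=0)
        assert len(s.probe_edges) >= 1

    @pytest.mark.parametrize("beta", [0, 100, -5])
    def test_beta_out_of_range(self, beta):
        with pytest.raises(ValueError):
            split_edges(FULL_EDGES, beta=beta, seed=0)

    def test_too_few_edges(self):
        with pytest.raises(ValueError):
            split_edges([("a", "b")], beta=50, seed=0)

    @given(st.integers(0, 2**31 - 1), st.integers(55, 95))
    def test_partition_invariants_under_seeds(self, seed, beta):
        s = split_edges(FULL_EDGES, beta=beta, seed=seed)
        norm = {tuple(sorted(e)) for e in FULL_EDGES}
        assert s.training_edges | s.probe_edges == norm
        assert s.training_edges.isdisjoint(s.probe_edges)
        assert s.non_existing.isdisjoint(norm)
        expected = min(max(int(np.floor(beta * 5 / 100 + 0.5)), 1), 4)
        assert len(s.training_edges) == expected


class TestAucExhaustive:
    def test_worked_example(self, split_example):
        g, probe, negatives = split_example
        pairs = negatives | {probe}
        scores = score_pairs(g, pairs, "dicn")
        res = auc_exhaustive(scores, [probe], negatives)
        assert (res.n, res.n1, res.n2) == (5, 3, 1)
        assert res.auc == 0.7

    def test_perfect_separation(self):
        scores = {("a", "p"): 2.0, ("a", "q"): 1.0, ("a", "r"): 0.5}
        res = auc_exhaustive(scores, [("a", "p")], [("a", "q"), ("a", "r")])
        assert res.auc == 1.0

    def test_all_ties(self):
        scores = {("a", "p"): 1.0, ("a", "q"): 1.0}
        res = auc_exhaustive(scores, [("a", "p")], [("a", "q")])
        assert res.auc == 0.5

    def test_float_noise_counts_as_tie(self):
        scores = {("a", "p"): 2.5, ("a", "q"): 2.5 + 1e-14}
        res = auc_exhaustive(scores, [("a", "p")], [("a", "q")])
        assert res.n2 == 1

    def test_missing_score_raises(self):
        with pytest.raises(KeyError):
            auc_exhaustive({}, [("a", "b")], [("c", "d")])

    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=40),
        st.lists(st.integers(0, 6), min_size=1, max_size=40),
    )
    def test_matches_double_loop_oracle(self, ps, qs):
        scores = {("p", str(k)): float(v) for k, v in enumerate(ps)}
        scores |= {("q", str(k)): float(v) for k, v in enumerate(qs)}
        probe = [("p", str(k)) for k in range(len(ps))]
        neg = [("q", str(k)) for k in range(len(qs))]
        res = auc_exhaustive(scores, probe, neg)
        n, n1, n2, auc = orc.auc_double_loop(
            [float(v) for v in ps], [float(v) for v in qs]
        )
        assert (res.n, res.n1, res.n2) == (n, n1, n2)
        assert res.auc == pytest.approx(auc)


class TestTrainingGraph:
    def test_probe_edges_absent(self):
        s = split_edges(FULL_EDGES, beta=80, seed=5)
        g = training_graph(s)
        got = {
            tuple(sorted((g.labels[i], g.labels[j]))) for i, j in g.edges()
        }
        assert got == s.training_edges
        assert g.n_nodes == 5  # full node universe survives the split

    def test_scores_independent_of_probe_edges(self):
        s = split_edges(FULL_EDGES, beta=80, seed=5)
        g = training_graph(s)
        g_pruned = build_graph(
            sorted(s.training_edges), nodes=[str(k) for k in range(1, 6)]
        )
        pairs = s.probe_edges | s.non_existing
        for method in ("cn", "dicn", "ccpa"):
            assert score_pairs(g, pairs, method) == score_pairs(
                g_pruned, pairs, method
            )


class TestFilters:
    def setup_method(self):
        from dicn import EdgeSplit

        fx, probe, negatives = train_probe_example()
        self.g = fx.graph()
        # the worked-example split, constructed explicitly
        self.split = EdgeSplit(
            training_edges=frozenset(fx.edges),
            probe_edges=frozenset({probe}),
            non_existing=frozenset(negatives),
            beta=80.0,
            seed=0,
        )

    def test_no_common_neighbour_filter_drops_probe(self):
        probe, neg = filter_no_common_neighbour(self.split, self.g)
        assert probe == set()  # CN(3,5)=1 on the training graph
        # every remaining negative has CN 0 and both degrees > 1
        for q in neg:
            i, j = self.g.index_of[q[0]], self.g.index_of[q[1]]
            assert len(self.g.adjacency[i] & self.g.adjacency[j]) == 0
            assert len(self.g.adjacency[i]) > 1 and len(self.g.adjacency[j]) > 1

    def test_degree_one_endpoint_excluded(self):
        # (4,5): both endpoints have training degree 1
        _, neg = filter_no_common_neighbour(self.split, self.g)
        assert ("4", "5") not in neg

    def test_star_graph_no_negatives_survive(self):
        edges = [("c", str(k)) for k in range(4)]
        s = split_edges(edges, beta=75, seed=1)
        g = training_graph(s)
        _, neg = filter_no_common_neighbour(s, g)
        # every leaf pair shares the centre, and the centre pairs fail degree
        assert all(
            len(g.adjacency[g.index_of[u]] & g.adjacency[g.index_of[v]]) == 0
            for u, v in neg
        )

    def test_equal_common_neighbour_comparisons(self):
        comps = filter_equal_common_neighbours(self.split, self.g)
        # probe (3,5) has CN 1; negatives with CN 1 on the training graph
        # are (1,3), (1,5) and (2,4)
        assert comps == {
            (("3", "5"), ("1", "3")),
            (("3", "5"), ("1", "5")),
            (("3", "5"), ("2", "4")),
        }

    def test_equal_cn_auc_over_comparisons(self):
        comps = filter_equal_common_neighbours(self.split, self.g)
        pairs = {p for p, _ in comps} | {q for _, q in comps}
        scores = score_pairs(self.g, pairs, "dicn")
        res = auc_over_comparisons(scores, comps)
        assert res.n == 3
        # 2.5 vs 2.5 (tie), 2.5 vs 2.0 (win), 2.5 vs 2.82 (loss)
        assert (res.n1, res.n2) == (1, 1)

    def test_empty_comparisons_reported_missing(self):
        assert auc_over_comparisons({}, []) is None


class TestRunExperiment:
    def test_repeatable_reports(self):
        g = planted_two_community_graph(24, 0.5, 0.05, seed=2)
        edges = [(g.labels[i], g.labels[j]) for i, j in g.edges()]
        a = run_experiment(edges, "cn", beta=80, repetitions=3, seed=9)
        b = run_experiment(edges, "cn", beta=80, repetitions=3, seed=9)
        assert [r.auc for r in a.results] == [r.auc for r in b.results]

    def test_cn_separates_planted_communities(self):
        g = planted_two_community_graph(30, 0.55, 0.04, seed=4)
        edges = [(g.labels[i], g.labels[j]) for i, j in g.edges()]
        rep = run_experiment(edges, "cn", beta=80, repetitions=5, seed=1)
        assert rep.mean_auc > 0.5

    def test_dicn_tracks_cn_on_planted_graphs(self):
        g = planted_two_community_graph(26, 0.5, 0.05, seed=7)
        edges = [(g.labels[i], g.labels[j]) for i, j in g.edges()]
        cn_rep = run_experiment(edges, "cn", beta=80, repetitions=4, seed=3)
        dicn_rep = run_experiment(edges, "dicn", beta=80, repetitions=4, seed=3)
        assert dicn_rep.mean_auc >= cn_rep.mean_auc - 0.05

    def test_beta_sweep_shapes(self):
        g = planted_two_community_graph(20, 0.5, 0.08, seed=5)
        edges = [(g.labels[i], g.labels[j]) for i, j in g.edges()]
        reports = [
            run_experiment(edges, "pa", beta=b, repetitions=2, seed=0)
            for b in (50, 60, 70, 80, 90)
        ]
        assert len(reports) == 5
        assert all(len(r.results) == 2 for r in reports)

    def test_restricted_experiments_run(self):
        g = planted_two_community_graph(20, 0.45, 0.08, seed=6)
        edges = [(g.labels[i], g.labels[j]) for i, j in g.edges()]
        for exp, method in ((3, "pa"), (4, "dicn")):
            rep = run_experiment(
                edges, method, beta=75, repetitions=2, seed=2, experiment=exp
            )
            for res in rep.results:
                assert res is None or 0.0 <= res.auc <= 1.0

    def test_unknown_method(self):
        with pytest.raises(KeyError):
            run_experiment(FULL_EDGES, "katz", repetitions=1)


class TestMotivationStats:
    def test_triangle_free_graph_all_zero_cn(self, toy):
        zero_frac, hist_e, hist_n = motivation_stats(toy)
        assert zero_frac == 1.0
        assert hist_e == {0: 4}

    def test_complete_graph_no_zero_cn(self):
        labels = list("abcd")
        g = build_graph(
            [(u, v) for i, u in enumerate(labels) for v in labels[i + 1:]]
        )
        zero_frac, hist_e, hist_n = motivation_stats(g)
        assert zero_frac == 0.0
        assert sum(hist_n.values()) == 0

    @given(st.integers(0, 10_000))
    def test_histogram_mass_conservation(self, seed):
        from dicn import random_uniform_graph

        g = random_uniform_graph(12, 0.3, seed % 100)
        _, hist_e, hist_n = motivation_stats(g)
        assert sum(hist_e.values()) == g.edge_count
        assert sum(hist_n.values()) == 12 * 11 // 2 - g.edge_count
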