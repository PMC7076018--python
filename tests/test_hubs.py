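"""Centralities, hub classification, and edge classes."""

import numpy as np
import pytest

from taskconnectome.core import Partition
from taskconnectome.gppi import DifferenceMatrix
from taskconnectome.hubs import (CentralityTable, HubSet, absolute_graph,
                                 centralities, edge_class_counts,
                                 hub_icn_test, hub_score_classify,
                                 kmeans_classify)

from conftest import random_difference_matrix


class TestAbsoluteGraph:
    def test_both_signs_become_edges(self, small_difference):
        g = absolute_graph(small_difference)
        assert g[0, 1] and g[4, 0]
        assert g.sum() == np.count_nonzero(small_difference.values)

    def test_all_zero_gives_empty(self):
        d = DifferenceMatrix(values=np.zeros((4, 4), dtype=int))
        assert absolute_graph(d).sum() == 0


class TestCentralities:
    def test_directed_star(self):
        # center 0 -> leaves 1..5
        n = 6
        adj = np.zeros((n, n), dtype=bool)
        adj[0, 1:] = True
        p = Partition(labels=np.zeros(n, dtype=int))
        t = centralities(adj, p)
        assert t.deg_out[0] == 5 and t.pl_out[0] == 1.0
        assert np.all(t.deg_out[1:] == 0)
        assert np.all(t.deg_in[1:] == 1)

    def test_three_cycle_betweenness(self):
        # 0->1->2->0: each node lies on exactly one 2-hop shortest path
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 2] = adj[2, 0] = True
        t = centralities(adj, Partition(labels=[0, 0, 0]))
        assert np.allclose(t.betweenness, 1.0)
        assert np.allclose(t.pl_out, 1.5)

    def test_participation_zero_when_all_edges_within_module(self):
        adj = np.zeros((6, 6), dtype=bool)
        adj[0, 1] = adj[0, 2] = True  # all out-edges inside module 0
        p = Partition(labels=[0, 0, 0, 1, 1, 1])
        t = centralities(adj, p)
        assert t.pc_out[0] == pytest.approx(0.0)

    def test_participation_even_split(self):
        # one edge into each of two modules -> pc = 1 - 2*(1/2)^2 = 0.5
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[0, 2] = True
        p = Partition(labels=[0, 0, 1, 1])
        t = centralities(adj, p)
        assert t.pc_out[0] == pytest.approx(0.5)

    def test_isolated_node_flagged(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = True
        t = centralities(adj, Partition(labels=[0, 0, 0]))
        assert t.deg_out[2] == 0 and t.pc_out[2] == 0
        assert np.isinf(t.pl_out[2])

    def test_betweenness_matches_networkx_manual(self, rng):
        import networkx as nx
        d = random_difference_matrix(rng, 12, p_edge=0.3)
        adj = absolute_graph(d)
        t = centralities(adj, Partition(labels=np.zeros(12, int)))
        g = nx.from_numpy_array(adj.astype(int), create_using=nx.DiGraph)
        ref = nx.betweenness_centrality(g, normalized=False)
        assert np.allclose(t.betweenness, [ref[i] for i in range(12)])


def brute_force_hub_scores(t: CentralityTable, top_fraction, min_measures,
                           min_reach=0.05):
    """Independent re-implementation: explicit rank-and-count per profile."""
    n = t.n_nodes
    count = int(np.floor(n * top_fraction))
    is_hub = np.zeros(n, dtype=bool)
    for direction in ("in", "out"):
        deg, btw, pc, pl = t.profile(direction)
        reach = t.reach_in if direction == "in" else t.reach_out
        pl = pl.copy()
        pl[reach < min_reach] = np.inf
        hits = np.zeros(n, dtype=int)
        for vals, asc in ((deg, False), (btw, False), (pc, False), (pl, True)):
            ranked = sorted(range(n),
                            key=lambda i: (vals[i] if asc else -vals[i], i))
            for i in ranked[:count]:
                hits[i] += 1
        is_hub |= hits >= min_measures
    return is_hub


class TestHubScoreClassify:
    def test_top_node_on_everything_is_hub(self):
        n = 9
        base = np.arange(n, dtype=float)
        t = CentralityTable(deg_in=base, deg_out=base, betweenness=base,
                            pc_in=base / n, pc_out=base / n,
                            pl_in=n - base, pl_out=n - base,
                            reach_in=np.ones(n), reach_out=np.ones(n))
        h = hub_score_classify(t)
        assert h.is_hub[n - 1]
        assert not h.is_hub[0]

    def test_two_of_four_is_not_enough(self):
        n = 9
        lo = np.zeros(n)
        hi = lo.copy()
        hi[0] = 1.0
        # node 0 tops degree and betweenness only; pc and pl are flat with
        # index tie-break, so node 0 is also in their top sets -> construct
        # pc/pl so node 0 ranks last
        pc = np.linspace(0, 1, n)   # node 0 least diverse
        pl = np.linspace(2, 1, n)   # node 0 longest paths
        t = CentralityTable(deg_in=hi, deg_out=lo, betweenness=hi,
                            pc_in=pc, pc_out=pc, pl_in=pl, pl_out=pl,
                            reach_in=np.ones(n), reach_out=np.ones(n))
        # in-profile: node 0 in top third for deg_in and betweenness only
        h = hub_score_classify(t)
        assert not h.is_hub[0]

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(50):
            n = int(rng.integers(10, 31))
            d = random_difference_matrix(rng, n, p_edge=0.25)
            p = Partition(labels=rng.integers(0, 3, size=n))
            t = centralities(absolute_graph(d), p)
            got = hub_score_classify(t).is_hub
            want = brute_force_hub_scores(t, 1 / 3, 3)
            assert np.array_equal(got, want)


class TestKMeansClassify:
    def _table(self, n_hubs=5, n_per=15, rng=None):
        rng = rng or np.random.default_rng(0)
        n = n_hubs + n_per
        deg = np.concatenate([rng.normal(20, 1, n_hubs), rng.normal(2, 1, n_per)])
        btw = np.concatenate([rng.normal(50, 5, n_hubs), rng.normal(5, 2, n_per)])
        pc = np.concatenate([rng.normal(0.8, .02, n_hubs), rng.normal(0.2, .05, n_per)])
        pl = np.concatenate([rng.normal(1.2, .05, n_hubs), rng.normal(3, .2, n_per)])
        return CentralityTable(deg_in=deg, deg_out=deg, betweenness=btw,
                               pc_in=pc, pc_out=pc, pl_in=pl, pl_out=pl,
                               reach_in=np.ones(n), reach_out=np.ones(n))

    def test_separable_groups_exactly_recovered(self):
        t = self._table()
        h = kmeans_classify(t, seed=0)
        assert np.array_equal(h.is_hub, np.arange(20) < 5)

    def test_deterministic_given_seed(self):
        t = self._table()
        assert np.array_equal(kmeans_classify(t, seed=3).is_hub,
                              kmeans_classify(t, seed=3).is_hub)

    def test_zero_variance_feature_dropped(self):
        t = self._table()
        t.betweenness[:] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            h = kmeans_classify(t, seed=0)
        assert np.array_equal(h.is_hub, np.arange(20) < 5)

    def test_agrees_with_hub_scores_on_separable_data(self):
        t = self._table()
        hs = hub_score_classify(t)
        km = kmeans_classify(t, seed=1)
        both = hs.is_hub & km.is_hub
        either = hs.is_hub | km.is_hub
        assert both.sum() / either.sum() >= 0.8


class TestHubIcnTest:
    def test_uniform_hubs_nothing_significant(self, rng):
        p = Partition(labels=np.repeat(np.arange(4), 10))
        is_hub = np.zeros(40, dtype=bool)
        is_hub[::4] = True  # evenly spread
        res = hub_icn_test(HubSet(is_hub=is_hub, method="hub_score"), p,
                           n_perm=500, seed=0)
        assert not any(v["significant"] for v in res.values())

    def test_concentrated_hubs_enriched_and_depleted(self):
        p = Partition(labels=np.repeat(np.arange(4), 10))
        is_hub = np.zeros(40, dtype=bool)
        is_hub[:10] = True  # all hubs in module 0
        res = hub_icn_test(HubSet(is_hub=is_hub, method="hub_score"), p,
                           n_perm=1999, seed=0)
        assert res[0]["p_high"] == 1 / 2000
        assert res[0]["significant"]
        assert all(res[m]["p_low"] < 0.05 for m in (1, 2, 3))


class TestEdgeClasses:
    def test_no_hubs_all_periphery(self, small_difference):
        h = HubSet(is_hub=np.zeros(5, dtype=bool), method="hub_score")
        c = edge_class_counts(small_difference, h)
        assert c["periphery_periphery"] == 4
        assert c["hub_hub"] == 0 and c["hub_periphery"] == 0

    def test_all_hubs_all_hub_hub(self, small_difference):
        h = HubSet(is_hub=np.ones(5, dtype=bool), method="hub_score")
        c = edge_class_counts(small_difference, h)
        assert c["hub_hub"] == 4

    def test_counts_sum_matches_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            d = random_difference_matrix(rng, n)
            hub = rng.random(n) < 0.3
            c = edge_class_counts(d, HubSet(is_hub=hub, method="hub_score"))
            total = sum(c.values())
            assert total == np.count_nonzero(d.values)
            # brute force classification
            hh = hp = pp = 0
            for i in range(n):
                for j in range(n):
                    if d.values[i, j] == 0:
                        continue
                    if hub[i] and hub[j]:
                        hh += 1
                    elif hub[i] or hub[j]:
                        hp += 1
                    else:
                        pp += 1
            assert (c["hub_hub"], c["hub_periphery"],
                    c["periphery_periphery"]) == (hh, hp, pp)
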