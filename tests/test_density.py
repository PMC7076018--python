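"""Densities, rewiring null, permutation tests, network degree."""

import numpy as np
import pytest

from taskconnectome.core import Partition, UNASSIGNED
from taskconnectome.density import (DensityMatrices, density_by_partition,
                                    density_permutation_test,
                                    network_degree_and_chi2,
                                    rewire_signed_directed)
from taskconnectome.gppi import DifferenceMatrix

from conftest import random_difference_matrix


def brute_force_density(values, labels, sign):
    """Independent edge-counting oracle."""
    target = 1 if sign == "+" else -1
    mods = sorted(set(labels) - {UNASSIGNED})
    K = len(mods)
    out = np.zeros((K, K))
    n = len(labels)
    for ai, a in enumerate(mods):
        for bi, b in enumerate(mods):
            count = denom = 0
            for i in range(n):
                for j in range(n):
                    if i == j or labels[i] != a or labels[j] != b:
                        continue
                    denom += 1
                    count += values[i, j] == target
            out[ai, bi] = count / denom if denom else np.nan
    return out


class TestDensity:
    def test_hand_counted_example(self, small_difference, small_partition):
        # A={0,1,2}, B={3,4}; positive edges 0->1, 1->2, 0->3
        pos = density_by_partition(small_difference, small_partition, "+")
        assert pos[0, 0] == pytest.approx(2 / 6)
        assert pos[0, 1] == pytest.approx(1 / 6)
        assert pos[1, 0] == 0.0
        neg = density_by_partition(small_difference, small_partition, "-")
        assert neg[1, 0] == pytest.approx(1 / 6)

    def test_empty_matrix_all_zero(self, small_partition):
        d = DifferenceMatrix(values=np.zeros((5, 5), dtype=int))
        assert np.all(density_by_partition(d, small_partition, "+") == 0)

    def test_complete_positive_matrix_all_ones(self, small_partition):
        v = np.ones((5, 5), dtype=int)
        d = DifferenceMatrix(values=v)
        assert np.allclose(density_by_partition(d, small_partition, "+"), 1.0)

    def test_singleton_module_within_density_nan(self):
        d = DifferenceMatrix(values=np.zeros((3, 3), dtype=int))
        p = Partition(labels=[0, 0, 1])
        dens = density_by_partition(d, p, "+")
        assert np.isnan(dens[1, 1])

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 30))
            d = random_difference_matrix(rng, n)
            labels = rng.integers(0, 4, size=n)
            labels[rng.random(n) < 0.1] = UNASSIGNED
            if len(set(labels) - {UNASSIGNED}) < 2:
                continue
            p = Partition(labels=labels)
            for sign in "+-":
                got = density_by_partition(d, p, sign)
                want = brute_force_density(d.values, list(labels), sign)
                assert np.allclose(got, want, equal_nan=True)


class TestRewiring:
    def test_signed_degrees_conserved_exactly(self, rng):
        for trial in range(20):
            d = random_difference_matrix(rng, 25, p_edge=0.2)
            r = rewire_signed_directed(d, seed=trial)
            for sign in (1, -1):
                assert np.array_equal((d.values == sign).sum(0),
                                      (r.values == sign).sum(0))
                assert np.array_equal((d.values == sign).sum(1),
                                      (r.values == sign).sum(1))

    def test_two_edge_graph_unique_swap(self):
        # exhaustive enumeration: a single swap of {0->1, 2->3} can only
        # yield {0->3, 2->1}
        from taskconnectome.density import _swap_edges
        rng = np.random.default_rng(0)
        edges = np.array([[0, 1], [2, 3]])
        occupied = {(0, 1), (2, 3)}
        performed, _ = _swap_edges(edges, occupied, 1, rng)
        assert performed == 1
        assert sorted(map(tuple, edges.tolist())) == [(0, 3), (2, 1)]
        # public API: reachable configurations are only the original and the
        # unique swapped graph
        v = np.zeros((4, 4), dtype=int)
        v[0, 1] = v[2, 3] = 1
        d = DifferenceMatrix(values=v)
        swapped = np.zeros((4, 4), dtype=int)
        swapped[0, 3] = swapped[2, 1] = 1
        allowed = {tuple(map(tuple, v.tolist())),
                   tuple(map(tuple, swapped.tolist()))}
        for seed in range(20):
            r = rewire_signed_directed(d, swaps_per_edge=1, seed=seed)
            assert tuple(map(tuple, r.values.tolist())) in allowed

    def test_fixed_seed_reproducible(self, rng):
        d = random_difference_matrix(rng, 20)
        a = rewire_signed_directed(d, seed=9)
        b = rewire_signed_directed(d, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_too_sparse_returns_input_with_warning(self):
        v = np.zeros((3, 3), dtype=int)
        v[0, 1] = 1
        d = DifferenceMatrix(values=v)
        with pytest.warns(UserWarning, match="sparse"):
            r = rewire_signed_directed(d, seed=0)
        assert np.array_equal(r.values, d.values)

    def test_signs_never_mix(self, rng):
        d = random_difference_matrix(rng, 20, p_edge=0.3)
        r = rewire_signed_directed(d, seed=4)
        assert (r.values == 1).sum() == (d.values == 1).sum()
        assert (r.values == -1).sum() == (d.values == -1).sum()


class TestPermutationTest:
    def test_planted_dense_block_enriched(self, rng):
        # all positive edges inside module 0 -> within-density enrichment
        n = 24
        v = np.zeros((n, n), dtype=int)
        for i in range(8):
            for j in range(8):
                if i != j and rng.random() < 0.6:
                    v[i, j] = 1
        # sprinkle a few edges elsewhere so rewiring has freedom
        for _ in range(10):
            i, j = rng.integers(0, n, 2)
            if i != j and v[i, j] == 0:
                v[i, j] = 1
        d = DifferenceMatrix(values=v)
        p = Partition(labels=np.repeat([0, 1, 2], 8))
        # n_perm large enough that the minimum attainable p clears the
        # Bonferroni level (alpha/2)/(2 K^2)
        dm = density_permutation_test(d, p, n_perm=1999, seed=0)
        assert dm.p_positive_high[0, 0] == 1 / 2000
        assert dm.significant("+")[0, 0]

    def test_pvalues_add_one_corrected(self, rng):
        d = random_difference_matrix(rng, 15)
        p = Partition(labels=np.repeat([0, 1, 2], 5))
        dm = density_permutation_test(d, p, n_perm=100, seed=1)
        for arr in (dm.p_positive_high, dm.p_positive_low,
                    dm.p_negative_high, dm.p_negative_low):
            assert np.all(arr > 0) and np.all(arr <= 1)
            assert np.all(arr >= 1 / 101)

    def test_minimum_permutations_enforced(self, small_difference,
                                           small_partition):
        with pytest.raises(ValueError, match="100"):
            density_permutation_test(small_difference, small_partition,
                                     n_perm=10)


class TestNetworkDegree:
    def _dm(self, sig_pos, K=12):
        # build a DensityMatrices with hand-set significance
        z = np.zeros((K, K))
        ph = np.ones((K, K))
        for cell in sig_pos:
            ph[cell] = 1e-9
        return DensityMatrices(positive=z, negative=z,
                               p_positive_high=ph, p_positive_low=np.ones((K, K)),
                               p_negative_high=np.ones((K, K)),
                               p_negative_low=np.ones((K, K)),
                               alpha=0.05)

    def test_uniform_degree_chi2_zero(self):
        # every module with the same degree -> chi2 == 0, p == 1
        K = 4
        dm = self._dm([(a, b) for a in range(K) for b in range(K) if a != b],
                      K=K)
        degree, chi2, df, p = network_degree_and_chi2(dm)
        assert len(set(degree.tolist())) == 1
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_skewed_vector(self):
        # degree vector (12,0,...,0) over K=12: chi2 = 121 + 11 = 132
        from scipy import stats
        observed = np.array([12] + [0] * 11)
        chi2, p = stats.chisquare(observed)
        assert chi2 == pytest.approx(132.0)
        # cross-check with our wiring: one module in 6 significant cells,
        # diagonal counted twice
        dm = self._dm([(0, 0)] * 1)
        degree, c, df, _ = network_degree_and_chi2(dm)
        assert degree[0] == 2 and degree.sum() == 2
        assert df == 11

    def test_off_diagonal_feeds_both_modules(self):
        dm = self._dm([(2, 7)])
        degree, *_ = network_degree_and_chi2(dm)
        assert degree[2] == 1 and degree[7] == 1

    def test_diagonal_once_option(self):
        dm = self._dm([(3, 3)])
        degree, *_ = network_degree_and_chi2(dm, diagonal="once")
        assert degree[3] == 1

    def test_all_zero_degree_nan(self):
        dm = self._dm([])
        with pytest.warns(UserWarning, match="undefined"):
            degree, chi2, df, p = network_degree_and_chi2(dm)
        assert np.isnan(chi2) and df == 11
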