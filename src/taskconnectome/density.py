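"""Network-level statistics on the difference matrix.

Within- and between-module edge densities per sign, a degree- and
sign-preserving rewiring null (double-edge swaps applied separately to the
positive and negative edge sets), permutation p-values Bonferroni-corrected
over 2 K^2 tests, module-level degree, and a chi-squared test of degree
uniformity across modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import Partition, UNASSIGNED
from .gppi import DifferenceMatrix

__all__ = ["DensityMatrices", "density_by_partition", "rewire_signed_directed",
           "density_permutation_test", "network_degree_and_chi2"]


@dataclass
class DensityMatrices:
    """K x K density proportions and permutation p-values per sign."""

    positive: np.ndarray
    negative: np.ndarray
    p_positive_high: np.ndarray = None
    p_positive_low: np.ndarray = None
    p_negative_high: np.ndarray = None
    p_negative_low: np.ndarray = None
    module_ids: np.ndarray = None
    alpha: float = 0.05
    n_perm: int = 0

    @property
    def n_modules(self) -> int:
        return self.positive.shape[0]

    @property
    def n_tests(self) -> int:
        # K*K cells per sign matrix
        return 2 * self.n_modules ** 2

    def significant(self, sign: str) -> np.ndarray:
        """Bonferroni-significant cells; two one-sided tests at alpha/2 each
        within the 2*K^2 family."""
        ph = self.p_positive_high if sign == "+" else self.p_negative_high
        pl = self.p_positive_low if sign == "+" else self.p_negative_low
        if ph is None:
            raise ValueError("no permutation p-values attached")
        thr = (self.alpha / 2) / self.n_tests
        return (ph <= thr) | (pl <= thr)


def density_by_partition(d: DifferenceMatrix, p: Partition, sign: str
                         ) -> np.ndarray:
    """Directed density of sign-matching edges within/between modules.

    Cell (a, b) is the number of edges from module a to module b with the
    requested sign over the number of possible ordered pairs
    (``n_a * (n_a - 1)`` on the diagonal, ``n_a * n_b`` off it). Modules of
    size one have undefined within-density (NaN). Unassigned nodes are
    excluded.
    """
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    if d.n_nodes != p.n_nodes:
        raise ValueError("difference matrix and partition sizes differ")
    target = 1 if sign == "+" else -1
    mods = p.module_ids
    K = mods.size
    out = np.zeros((K, K))
    match = d.values == target
    for ai, a in enumerate(mods):
        na = p.members(int(a))
        for bi, b in enumerate(mods):
            nb = p.members(int(b))
            count = match[np.ix_(na, nb)].sum()
            if ai == bi:
                denom = na.size * (na.size - 1)
                out[ai, bi] = count / denom if denom else np.nan
            else:
                out[ai, bi] = count / (na.size * nb.size)
    return out


def _swap_edges(edges: np.ndarray, occupied: set, n_swaps_target: int,
                rng: np.random.Generator):
    """In-place double-edge swaps preserving in/out degrees.

    ``occupied`` holds every (i, j) cell taken by *any* sign, so rewired
    positive edges never land on negative cells and vice versa.
    """
    m = len(edges)
    performed = attempts = 0
    max_attempts = max(20 * n_swaps_target, 100)
    chunk = iter(())
    while performed < n_swaps_target and attempts < max_attempts:
        attempts += 1
        try:
            e1, e2 = next(chunk)
        except StopIteration:
            chunk = iter(rng.integers(0, m, size=(256, 2)))
            e1, e2 = next(chunk)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        # proposed: a->d, c->b
        if a == d or c == b or a == c or b == d:
            continue
        if (a, d) in occupied or (c, b) in occupied:
            continue
        occupied.discard((a, b))
        occupied.discard((c, d))
        occupied.add((a, d))
        occupied.add((c, b))
        edges[e1, 1] = d
        edges[e2, 1] = b
        performed += 1
    return performed, attempts


def rewire_signed_directed(d: DifferenceMatrix, swaps_per_edge: int = 10,
                           seed=None) -> DifferenceMatrix:
    """Degree-preserving randomization of a signed directed ternary matrix.

    Positive and negative edge sets are rewired independently by double-edge
    swaps; per node the in- and out-degree within each sign is preserved
    exactly. The target number of successful swaps per sign is
    ``swaps_per_edge`` times that sign's edge count.
    """
    rng = np.random.default_rng(seed)
    v = d.values
    occupied = set(map(tuple, np.argwhere(v != 0)))
    new_edges = {}
    total_performed = 0
    for sign in (1, -1):
        edges = np.argwhere(v == sign)
        if len(edges) < 2:
            new_edges[sign] = edges
            continue
        performed, _ = _swap_edges(edges, occupied,
                                   swaps_per_edge * len(edges), rng)
        total_performed += performed
        new_edges[sign] = edges
    if total_performed == 0 and np.count_nonzero(v):
        warnings.warn("graph too sparse to rewire; returning input unchanged")
        return DifferenceMatrix(values=v.copy(), alpha=d.alpha, n_tests=d.n_tests)
    out = np.zeros_like(v)
    for sign, edges in new_edges.items():
        for i, j in edges:
            out[i, j] = sign
    return DifferenceMatrix(values=out, alpha=d.alpha, n_tests=d.n_tests)


def density_permutation_test(d: DifferenceMatrix, p: Partition,
                             n_perm: int = 1000, alpha: float = 0.05,
                             swaps_per_edge: int = 10, seed=None
                             ) -> DensityMatrices:
    """Permutation p-values for every density cell against the rewiring null.

    Two one-sided add-one-corrected p-values per cell:
    ``p_high = (1 + #{null >= observed}) / (1 + n_perm)`` for enrichment and
    the analogue for depletion; significance is assessed at
    ``alpha / (2 * 2K^2)`` (two one-sided tests inside the 2K^2-test
    Bonferroni family).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    obs_pos = density_by_partition(d, p, "+")
    obs_neg = density_by_partition(d, p, "-")
    ge_pos = np.zeros_like(obs_pos)
    le_pos = np.zeros_like(obs_pos)
    ge_neg = np.zeros_like(obs_neg)
    le_neg = np.zeros_like(obs_neg)
    seeds = np.random.SeedSequence(seed).spawn(n_perm)
    for s in seeds:
        null = rewire_signed_directed(d, swaps_per_edge=swaps_per_edge, seed=s)
        np_pos = density_by_partition(null, p, "+")
        np_neg = density_by_partition(null, p, "-")
        with np.errstate(invalid="ignore"):
            ge_pos += np_pos >= obs_pos
            le_pos += np_pos <= obs_pos
            ge_neg += np_neg >= obs_neg
            le_neg += np_neg <= obs_neg
    def _p(counts):
        return (1.0 + counts) / (1.0 + n_perm)
    return DensityMatrices(
        positive=obs_pos, negative=obs_neg,
        p_positive_high=_p(ge_pos), p_positive_low=_p(le_pos),
        p_negative_high=_p(ge_neg), p_negative_low=_p(le_neg),
        module_ids=p.module_ids, alpha=alpha, n_perm=n_perm)


def network_degree_and_chi2(dm: DensityMatrices, diagonal: str = "twice"):
    """Module-level degree over significant density cells + uniformity test.

    Each significant off-diagonal cell (a, b), in either sign matrix, adds one
    out-degree to a and one in-degree to b; a significant diagonal cell adds
    one in and one out to its module (``diagonal='twice'``) or one total
    (``'once'``). Returns (degree vector, chi2, df, p) against the uniform
    expectation.
    """
    if diagonal not in ("twice", "once"):
        raise ValueError("diagonal must be 'twice' or 'once'")
    K = dm.n_modules
    degree = np.zeros(K, dtype=int)
    any_sig = False
    for sign in ("+", "-"):
        sig = dm.significant(sign)
        any_sig = any_sig or sig.any()
        for a in range(K):
            for b in range(K):
                if not sig[a, b]:
                    continue
                if a == b:
                    degree[a] += 2 if diagonal == "twice" else 1
                else:
                    degree[a] += 1
                    degree[b] += 1
    if not any_sig:
        warnings.warn("no significant density cells: chi2 undefined")
        return degree, np.nan, K - 1, np.nan
    chi2, p = stats.chisquare(degree)
    return degree, float(chi2), K - 1, float(p)
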