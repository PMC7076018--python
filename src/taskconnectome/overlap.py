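"""Overlap of hub sets with reference region sets, and association scores.

Jaccard index with a permutation null (hubs re-drawn uniformly across the
parcellation), its analytic upper bound given the two set sizes, odds ratio
with a Wald confidence interval on the log scale, and hub-versus-non-hub
comparisons of per-node meta-analytic association scores by permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Partition, UNASSIGNED
from .hubs import HubSet

__all__ = ["NodeSet", "OverlapResult", "jaccard", "max_jaccard",
           "jaccard_permutation_p", "contingency_table", "odds_ratio",
           "overlap_analysis", "association_comparison"]


@dataclass(frozen=True)
class NodeSet:
    """A set of node indices within a universe of N nodes."""

    members: frozenset
    universe: int

    def __init__(self, members, universe: int):
        members = frozenset(int(m) for m in members)
        if members and (min(members) < 0 or max(members) >= universe):
            raise ValueError("members outside universe")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "universe", int(universe))

    @classmethod
    def from_mask(cls, mask) -> "NodeSet":
        mask = np.asarray(mask, dtype=bool)
        return cls(np.nonzero(mask)[0], mask.size)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OverlapResult:
    jaccard: float
    jaccard_max: float
    jaccard_p: float
    contingency: tuple  # (both, a_only, b_only, neither)
    odds_ratio: float
    ci95: tuple


def _check_universe(a: NodeSet, b: NodeSet):
    if a.universe != b.universe:
        raise ValueError(f"universe mismatch: {a.universe} vs {b.universe}")


def jaccard(a: NodeSet, b: NodeSet) -> float:
    """Intersection over union; 0 when both sets are empty."""
    _check_universe(a, b)
    union = a.members | b.members
    if not union:
        return 0.0
    return len(a.members & b.members) / len(union)


def max_jaccard(size_a: int, size_b: int) -> float:
    """Largest possible Jaccard index for two sets of the given sizes."""
    if size_a < 0 or size_b < 0:
        raise ValueError("sizes must be non-negative")
    if size_a == 0 or size_b == 0:
        return 0.0
    return min(size_a, size_b) / max(size_a, size_b)


def jaccard_permutation_p(a: NodeSet, b: NodeSet, n_perm: int = 10000,
                          seed=None, two_sided: bool = False,
                          randomized: bool = False) -> float:
    """Permutation p for the observed Jaccard of ``a`` with ``b``.

    The null re-draws a set of size ``|a|`` uniformly from the universe and
    recomputes its Jaccard with ``b``. One-sided (enrichment) by default:
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.

    The Jaccard statistic is discrete, so this add-one p is valid but
    super-uniform under the null. ``randomized=True`` returns the classical
    randomized-test p, ``(#{null > obs} + U (1 + #{null = obs})) / (1 +
    n_perm)`` with U ~ Uniform(0, 1), which is exactly uniform under the
    null; use it for calibration checks, not for inference.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    _check_universe(a, b)
    obs = jaccard(a, b)
    rng = np.random.default_rng(seed)
    b_mask = np.zeros(b.universe, dtype=bool)
    b_mask[list(b.members)] = True
    nb = len(b)
    na = len(a)
    gt = eq = le = 0
    for _ in range(n_perm):
        draw = rng.choice(a.universe, size=na, replace=False)
        inter = int(b_mask[draw].sum())
        j = inter / (na + nb - inter) if (na + nb - inter) else 0.0
        gt += j > obs
        eq += j == obs
        le += j <= obs
    if randomized:
        u = rng.uniform()
        return float((gt + u * (1 + eq)) / (1 + n_perm))
    p_high = (1 + gt + eq) / (1 + n_perm)
    if not two_sided:
        return float(p_high)
    p_low = (1 + le) / (1 + n_perm)
    return float(min(1.0, 2 * min(p_high, p_low)))


def contingency_table(a: NodeSet, b: NodeSet) -> tuple:
    """2x2 counts over the universe: (both, a_only, b_only, neither)."""
    _check_universe(a, b)
    both = len(a.members & b.members)
    a_only = len(a) - both
    b_only = len(b) - both
    neither = a.universe - both - a_only - b_only
    return (both, a_only, b_only, neither)


def odds_ratio(contingency) -> tuple:
    """Cross-product odds ratio with a Wald 95% CI on the log scale.

    Zero cells get the Haldane-Anscombe +0.5 correction (flagged by a
    warning); a row or column with two zero cells leaves the ratio undefined.
    """
    a, b, c, d = (float(x) for x in contingency)
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    rows_cols = [(a, b), (c, d), (a, c), (b, d)]
    if any(x == 0 and y == 0 for x, y in rows_cols):
        raise ValueError("odds ratio undefined: a row or column is all zero")
    if min(a, b, c, d) == 0:
        warnings.warn("zero cell: applying Haldane-Anscombe +0.5 correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(oratio) - 1.96 * se))
    hi = float(np.exp(np.log(oratio) + 1.96 * se))
    return float(oratio), (lo, hi)


def overlap_analysis(hubs: NodeSet, reference: NodeSet, n_perm: int = 10000,
                     seed=None) -> OverlapResult:
    """Full overlap summary of a hub set against a reference region set."""
    j = jaccard(hubs, reference)
    jp = jaccard_permutation_p(hubs, reference, n_perm=n_perm, seed=seed)
    table = contingency_table(hubs, reference)
    oratio, ci = odds_ratio(table)
    return OverlapResult(jaccard=j, jaccard_max=max_jaccard(len(hubs), len(reference)),
                         jaccard_p=jp, contingency=table,
                         odds_ratio=oratio, ci95=ci)


def association_comparison(scores: np.ndarray, h: HubSet, p: Partition,
                           n_perm: int = 10000, alpha: float = 0.05,
                           seed=None) -> dict:
    """Hub minus non-hub mean association score, globally and per module.

    The null shuffles hub labels (within the module for the per-module
    tests); significance when the observed difference exceeds the null in
    ``1 - alpha`` of permutations, per-module p-values Bonferroni-corrected
    over the module count.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite for all nodes")
    if scores.size != h.is_hub.size or scores.size != p.n_nodes:
        raise ValueError("scores, hub set, and partition must align")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    K = p.n_modules

    def _one(mask):
        hubs = h.is_hub & mask
        non = ~h.is_hub & mask
        if hubs.sum() == 0 or non.sum() == 0:
            warnings.warn("group without hubs or non-hubs: NaN result")
            return np.nan, np.nan
        obs = scores[hubs].mean() - scores[non].mean()
        idx = np.nonzero(mask)[0]
        flags = h.is_hub[idx]
        ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(flags)
            diff = scores[idx][perm].mean() - scores[idx][~perm].mean()
            ge += diff >= obs
        return float(obs), float((1 + ge) / (1 + n_perm))

    out = {}
    obs, pval = _one(np.ones(scores.size, dtype=bool))
    out["global"] = {"difference": obs, "p": pval,
                     "significant": bool(pval <= alpha) if np.isfinite(pval) else False}
    for m in p.module_ids:
        obs, pval = _one(p.labels == m)
        corrected = min(pval * K, 1.0) if np.isfinite(pval) else np.nan
        out[int(m)] = {"difference": obs, "p": pval,
                       "p_bonferroni": corrected,
                       "significant": bool(corrected <= alpha)
                       if np.isfinite(corrected) else False}
    return out
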