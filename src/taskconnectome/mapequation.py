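"""Two-level map equation and a greedy node-moving optimizer.

The map equation scores a partition M of a weighted undirected graph by the
expected per-step description length of a random walk under a two-level
Huffman coding scheme:

    L(M) = plogp(q) - 2 * sum_m plogp(q_m) - sum_i plogp(p_i)
           + sum_m plogp(q_m + sum_{i in m} p_i)

with plogp(x) = x log2 x, node visit rates p_i = s_i / (2W) (s_i node
strength, W total edge weight), module exit probabilities
q_m = cut_m / (2W) (cut_m the weight of edges leaving module m), and
q = sum_m q_m. Minimizing L favours modules that trap the walk.

The optimizer is Louvain-style: seeded random sweeps of single-node moves to
neighbouring modules, followed by module aggregation into super-nodes
(internal weight becomes a self-loop), repeated until no move improves the
description length. Deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["map_equation", "optimize_map_equation"]


def _plogp(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log2(x[pos])
    return out if out.ndim else float(out)


def map_equation(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Description length (bits/step) of a partition; direct from definition.

    Self-loop weight on the diagonal counts twice towards node strength and
    never towards module exit, matching random-walk conventions.
    """
    A = np.asarray(adjacency, dtype=float)
    labels = np.asarray(labels)
    if np.any(A < 0):
        raise ValueError("map equation requires non-negative weights")
    strength = A.sum(axis=1) + np.diag(A)
    two_w = strength.sum()
    if two_w == 0:
        return 0.0
    p = strength / two_w
    mods = np.unique(labels)
    q_m = np.empty(mods.size)
    p_m = np.empty(mods.size)
    for k, m in enumerate(mods):
        in_m = labels == m
        q_m[k] = A[np.ix_(in_m, ~in_m)].sum() / two_w
        p_m[k] = p[in_m].sum()
    q = q_m.sum()
    return float(_plogp(q) - 2 * _plogp(q_m).sum() - _plogp(p).sum()
                 + _plogp(q_m + p_m).sum())


class _Level:
    """One aggregation level: sparse neighbor lists + module statistics."""

    def __init__(self, A: np.ndarray):
        n = A.shape[0]
        self.n = n
        self.neighbors = []
        self.weights = []
        off = A.copy()
        np.fill_diagonal(off, 0.0)
        for i in range(n):
            nz = np.nonzero(off[i])[0]
            self.neighbors.append(nz)
            self.weights.append(off[i, nz])
        self.s_ext = off.sum(axis=1)            # strength without self-loops
        self.strength = self.s_ext + 2 * np.diag(A)
        self.two_w = self.strength.sum()
        self.labels = np.arange(n)
        self.p_m = self.strength / self.two_w if self.two_w else np.zeros(n)
        self.q_m = self.s_ext / self.two_w if self.two_w else np.zeros(n)

    def link_to_modules(self, i) -> dict:
        acc: dict[int, float] = {}
        for j, w in zip(self.neighbors[i], self.weights[i]):
            m = self.labels[j]
            acc[m] = acc.get(m, 0.0) + w
        return acc

    def _terms(self, q_a, p_a, q_b, p_b, q_tot):
        return (_plogp(q_tot) - 2 * (_plogp(q_a) + _plogp(q_b))
                + _plogp(q_a + p_a) + _plogp(q_b + p_b))

    def move_delta(self, i, target, w_to) -> float:
        a = self.labels[i]
        if target == a:
            return 0.0
        p_i = self.strength[i] / self.two_w
        e_i = self.s_ext[i] / self.two_w
        w_ia = w_to.get(a, 0.0) / self.two_w
        w_ib = w_to.get(target, 0.0) / self.two_w
        q_a, q_b = self.q_m[a], self.q_m[target]
        p_a, p_b = self.p_m[a], self.p_m[target]
        q_a_new = q_a - (e_i - w_ia) + w_ia
        q_b_new = q_b + (e_i - w_ib) - w_ib
        q_old = self.q_m.sum()
        q_new = q_old + (q_a_new - q_a) + (q_b_new - q_b)
        old = self._terms(q_a, p_a, q_b, p_b, q_old)
        new = self._terms(q_a_new, p_a - p_i, q_b_new, p_b + p_i, q_new)
        return new - old

    def apply_move(self, i, target, w_to):
        a = self.labels[i]
        p_i = self.strength[i] / self.two_w
        e_i = self.s_ext[i] / self.two_w
        w_ia = w_to.get(a, 0.0) / self.two_w
        w_ib = w_to.get(target, 0.0) / self.two_w
        self.q_m[a] = self.q_m[a] - (e_i - w_ia) + w_ia
        self.q_m[target] = self.q_m[target] + (e_i - w_ib) - w_ib
        self.p_m[a] -= p_i
        self.p_m[target] += p_i
        self.labels[i] = target

    def sweep(self, rng) -> bool:
        """One randomized pass of best single-node moves; True if any move."""
        moved = False
        for i in rng.permutation(self.n):
            if self.strength[i] == 0:
                continue
            w_to = self.link_to_modules(i)
            best, best_delta = self.labels[i], -1e-12
            for target in w_to:
                d = self.move_delta(i, target, w_to)
                if d < best_delta:
                    best, best_delta = target, d
            if best != self.labels[i]:
                self.apply_move(i, best, w_to)
                moved = True
        return moved


def _compress(labels: np.ndarray) -> np.ndarray:
    return np.unique(labels, return_inverse=True)[1]


def _aggregate(A: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Module graph: off-diagonal = between weight, diagonal = internal
    (so that super-node strengths equal summed member strengths)."""
    k = labels.max() + 1
    onehot = np.zeros((A.shape[0], k))
    onehot[np.arange(A.shape[0]), labels] = 1.0
    agg = onehot.T @ A @ onehot
    # agg's diagonal holds 2*internal_edges + original self-loops (once);
    # store internal_edges + self_loops so super strengths sum correctly
    self_loops = onehot.T @ np.diag(A)
    diag = (np.diag(agg) - self_loops) / 2 + self_loops
    out = agg.copy()
    np.fill_diagonal(out, diag)
    return out


def optimize_map_equation(adjacency: np.ndarray, seed=None) -> np.ndarray:
    """Minimize the two-level map equation; returns integer node labels."""
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(A < 0):
        raise ValueError("negative weights not allowed")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    if n == 0 or A.sum() == 0:
        return np.zeros(n, dtype=int)

    node_to_super = np.arange(n)
    work = A
    while True:
        level = _Level(work)
        improved = False
        for _ in range(200):
            if not level.sweep(rng):
                break
            improved = True
        labels = _compress(level.labels)
        node_to_super = labels[node_to_super]
        if not improved or labels.max() + 1 == work.shape[0]:
            break
        work = _aggregate(work, labels)
    return _compress(node_to_super)
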