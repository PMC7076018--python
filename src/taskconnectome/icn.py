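"""Intrinsic connectivity networks from resting partial correlations.

Pipeline: per subject, a Ledoit-Wolf-shrunk partial-correlation matrix
(Fisher z-transformed) is proportionally thresholded and clustered many times
with the stochastic map-equation optimizer; co-assignment frequencies form a
subject consensus matrix. Subject consensus matrices are averaged, the
average is thresholded again, and the optimizer runs on it; the modal
partition across those runs is the group partition. Nodes isolated after
group thresholding, or whose modal module is unstable across runs (< 50%),
are left unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import LedoitWolf

from .core import Partition, RoiTimeSeries, UNASSIGNED
from .mapequation import optimize_map_equation

__all__ = [
    "ConnectivityMatrix", "ConsensusMatrix", "partial_correlation_lw",
    "proportional_threshold", "detect_communities", "co_assignment",
    "consensus_cluster",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric matrix of Fisher-z partial correlations, zero diagonal."""

    values: np.ndarray
    node_ids: list = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix must be finite")
        np.fill_diagonal(v, 0.0)
        self.values = v
        if self.node_ids is None:
            self.node_ids = [f"roi{i:03d}" for i in range(v.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class ConsensusMatrix:
    """Co-assignment frequencies across optimizer runs; diagonal one."""

    values: np.ndarray
    n_runs: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("consensus entries must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(self.values, 1.0)


def partial_correlation_lw(ts: RoiTimeSeries, shrinkage: float | None = None
                           ) -> ConnectivityMatrix:
    """Fisher-z partial correlations from a shrunk precision matrix.

    The covariance is shrunk toward a scaled identity with the analytic
    Ledoit-Wolf intensity (or a forced ``shrinkage`` in [0, 1]); partial
    correlations are read off the negated standardized inverse:
    rho_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj).
    """
    X = ts.values
    if X.shape[0] <= 3:
        raise ValueError("need more than 3 time points")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.node_ids[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant time series for node(s): {bad}")
    if shrinkage is None:
        cov = LedoitWolf(assume_centered=False).fit(X).covariance_
    else:
        if not (0 <= shrinkage <= 1):
            raise ValueError("shrinkage must be in [0, 1]")
        s = np.cov(X, rowvar=False, ddof=0)
        mu = np.trace(s) / s.shape[0]
        cov = (1 - shrinkage) * s + shrinkage * mu * np.eye(s.shape[0])
    omega = np.linalg.inv(cov)
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    z = np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
    return ConnectivityMatrix(values=(z + z.T) / 2, node_ids=list(ts.node_ids))


def proportional_threshold(matrix, cost: float) -> np.ndarray:
    """Keep the ``cost`` fraction of strongest undirected edges.

    Retains the ``floor(cost * N(N-1)/2)`` largest *signed* values of the
    upper triangle (ties broken by descending weight then lexicographic node
    pair, deterministically), zeroing everything else. Negative survivors are
    zeroed with a warning, since the community detector requires non-negative
    weights.
    """
    v = matrix.values if hasattr(matrix, "values") else np.asarray(matrix, float)
    if not (0 < cost < 1):
        raise ValueError("cost must be in (0, 1)")
    n = v.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = v[iu, ju]
    keep = int(np.floor(cost * n * (n - 1) / 2))
    out = np.zeros_like(v)
    if keep == 0:
        warnings.warn("cost retains zero edges: empty graph")
        return out
    order = np.lexsort((ju, iu, -w))  # weight desc, then (i, j) lexicographic
    sel = order[:keep]
    n_neg = int(np.sum(w[sel] < 0))
    if n_neg:
        warnings.warn(f"{n_neg} retained edges were negative and set to zero")
    pos = sel[w[sel] > 0]
    out[iu[pos], ju[pos]] = w[pos]
    out[ju[pos], iu[pos]] = w[pos]
    return out


def detect_communities(adjacency: np.ndarray, n_runs: int, seed=None
                       ) -> list[np.ndarray]:
    """Independent stochastic map-equation partitions.

    Returns ``n_runs`` label arrays; isolated nodes are UNASSIGNED. An empty
    graph yields a single all-UNASSIGNED partition.
    """
    A = np.asarray(adjacency, dtype=float)
    if np.any(A < 0):
        raise ValueError("negative edge weights must be removed upstream")
    n = A.shape[0]
    isolated = A.sum(axis=1) == 0
    if isolated.all():
        return [np.full(n, UNASSIGNED, dtype=int)]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(n_runs)
    out = []
    for s in seeds:
        labels = optimize_map_equation(A, seed=s).astype(int)
        labels[isolated] = UNASSIGNED
        out.append(labels)
    return out


def co_assignment(partitions: list[np.ndarray]) -> ConsensusMatrix:
    """Fraction of runs in which node pairs share a (non-UNASSIGNED) label."""
    n = partitions[0].size
    acc = np.zeros((n, n))
    for lab in partitions:
        assigned = lab != UNASSIGNED
        same = (lab[:, None] == lab[None, :]) & assigned[:, None] & assigned[None, :]
        acc += same
    acc /= len(partitions)
    np.fill_diagonal(acc, 1.0)
    return ConsensusMatrix(values=acc, n_runs=len(partitions))


def _align(reference: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Relabel ``labels`` modules to best-overlap modules of ``reference``."""
    out = np.full_like(labels, UNASSIGNED)
    next_extra = (reference.max() + 1) if reference.size else 0
    for m in np.unique(labels):
        if m == UNASSIGNED:
            continue
        members = labels == m
        ref = reference[members]
        ref = ref[ref != UNASSIGNED]
        if ref.size:
            vals, counts = np.unique(ref, return_counts=True)
            out[members] = vals[np.argmax(counts)]
        else:
            out[members] = next_extra
            next_extra += 1
    return out


def consensus_cluster(matrices: list[ConnectivityMatrix],
                      subject_cost: float = 0.035, subject_runs: int = 100,
                      group_threshold: float = 0.07, group_runs: int = 200,
                      seed=None, stability: float = 0.5) -> Partition:
    """Group partition by two-stage consensus clustering.

    Per subject: proportional threshold at ``subject_cost``, ``subject_runs``
    stochastic partitions, co-assignment matrix. Across subjects: average the
    consensus matrices, threshold at ``group_threshold``, run the detector
    ``group_runs`` times, return the modal partition. A node is UNASSIGNED if
    isolated after group thresholding or if its modal module (after aligning
    runs to the modal partition) occurs in fewer than ``stability`` of runs.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 subjects")
    node_ids = matrices[0].node_ids
    for m in matrices[1:]:
        if m.node_ids != node_ids:
            raise ValueError("node ids differ across subjects")
    seeds = np.random.SeedSequence(seed).spawn(len(matrices) + 1)
    consensus = []
    for m, s in zip(matrices, seeds[:-1]):
        thr = proportional_threshold(m, subject_cost)
        parts = detect_communities(thr, subject_runs, seed=s)
        consensus.append(co_assignment(parts).values)
    avg = np.mean(consensus, axis=0)
    np.fill_diagonal(avg, 1.0)
    group_adj = proportional_threshold(avg, group_threshold)
    isolated = group_adj.sum(axis=1) == 0
    parts = detect_communities(group_adj, group_runs, seed=seeds[-1])

    # modal partition across runs (up to relabeling)
    canon = [tuple(Partition(labels=p).relabel_canonical().labels) for p in parts]
    uniq, counts = np.unique(np.asarray(canon, dtype=int), axis=0,
                             return_counts=True)
    modal = uniq[np.argmax(counts)].copy()

    # per-node stability: fraction of runs agreeing with the modal module
    aligned = np.stack([_align(modal, p) for p in parts])
    agree = (aligned == modal[None, :]).mean(axis=0)
    labels = modal.copy()
    labels[agree < stability] = UNASSIGNED
    labels[isolated] = UNASSIGNED
    part = Partition(labels=labels, node_ids=list(node_ids))
    return part.relabel_canonical()
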