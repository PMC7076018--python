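"""Hub classification from centrality profiles of the difference matrix.

The absolute (unsigned) difference matrix defines a directed unweighted
graph. Four centrality measures are computed per direction profile: degree,
participation coefficient (using the intrinsic-network partition),
betweenness (direction-symmetric, shared between profiles), and nodal path
length. A node is a hub when it ranks in the top third on at least three of
the four measures of either profile (hub-scores), or falls in the
high-centrality cluster of a k=2 k-means on either profile's standardized
measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path
from sklearn.cluster import KMeans

from .core import Partition, UNASSIGNED
from .gppi import DifferenceMatrix

__all__ = ["CentralityTable", "HubSet", "absolute_graph", "centralities",
           "hub_score_classify", "kmeans_classify", "hub_icn_test",
           "edge_class_counts"]


@dataclass
class CentralityTable:
    """Per-node directed centrality measures (``np.inf`` = unreachable)."""

    deg_in: np.ndarray
    deg_out: np.ndarray
    betweenness: np.ndarray
    pc_in: np.ndarray
    pc_out: np.ndarray
    pl_in: np.ndarray
    pl_out: np.ndarray
    reach_in: np.ndarray = None   # fraction of nodes that can reach i
    reach_out: np.ndarray = None  # fraction of nodes reachable from i

    @property
    def n_nodes(self) -> int:
        return self.deg_in.size

    def profile(self, direction: str):
        """(degree, betweenness, participation, path length) for a profile."""
        if direction == "in":
            return self.deg_in, self.betweenness, self.pc_in, self.pl_in
        if direction == "out":
            return self.deg_out, self.betweenness, self.pc_out, self.pl_out
        raise ValueError("direction must be 'in' or 'out'")


@dataclass
class HubSet:
    """Boolean hub flags with the method and parameters that produced them."""

    is_hub: np.ndarray
    method: str
    params: dict = None

    def __post_init__(self):
        self.is_hub = np.asarray(self.is_hub, dtype=bool)
        self.params = self.params or {}

    @property
    def n_hubs(self) -> int:
        return int(self.is_hub.sum())

    def indices(self) -> np.ndarray:
        return np.nonzero(self.is_hub)[0]


def absolute_graph(d: DifferenceMatrix) -> np.ndarray:
    """Boolean adjacency: edge wherever the difference matrix is nonzero."""
    return d.values != 0


def _participation(adj: np.ndarray, labels: np.ndarray, axis: int) -> np.ndarray:
    """1 - sum over modules of squared per-module degree fractions.

    ``axis=1`` gives the out-profile (row sums), ``axis=0`` the in-profile.
    Unassigned neighbours count as one extra group.
    """
    n = adj.shape[0]
    mods = list(np.unique(labels))
    pc = np.zeros(n)
    deg = adj.sum(axis=axis)
    for m in mods:
        sel = labels == m
        km = adj[:, sel].sum(axis=1) if axis == 1 else adj[sel, :].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            pc += np.where(deg > 0, (km / np.maximum(deg, 1)) ** 2, 0.0)
    return np.where(deg > 0, 1.0 - pc, 0.0)


def centralities(adj: np.ndarray, p: Partition) -> CentralityTable:
    """Directed centrality table of an unweighted graph.

    Betweenness counts shortest-path memberships with fractional credit for
    ties (it has no in/out variant and is shared between the two profiles);
    path lengths average over reachable targets (sources) only.
    """
    A = np.asarray(adj, dtype=bool)
    n = A.shape[0]
    if p.n_nodes != n:
        raise ValueError("partition must cover all graph nodes")
    deg_out = A.sum(axis=1)
    deg_in = A.sum(axis=0)
    g = nx.from_numpy_array(A.astype(int), create_using=nx.DiGraph)
    btw = np.array([v for _, v in sorted(
        nx.betweenness_centrality(g, normalized=False).items())])
    pc_out = _participation(A, p.labels, axis=1)
    pc_in = _participation(A, p.labels, axis=0)
    dist = shortest_path(A.astype(np.int8), method="D", unweighted=True)
    finite = np.isfinite(dist)
    np.fill_diagonal(finite, False)
    with np.errstate(invalid="ignore"):
        reach_out = finite.sum(axis=1) / max(n - 1, 1)
        reach_in = finite.sum(axis=0) / max(n - 1, 1)
        pl_out = np.where(finite.sum(axis=1) > 0,
                          np.where(finite, dist, 0).sum(axis=1)
                          / np.maximum(finite.sum(axis=1), 1), np.inf)
        pl_in = np.where(finite.sum(axis=0) > 0,
                         np.where(finite, dist, 0).sum(axis=0)
                         / np.maximum(finite.sum(axis=0), 1), np.inf)
    return CentralityTable(deg_in=deg_in.astype(float),
                           deg_out=deg_out.astype(float),
                           betweenness=btw.astype(float),
                           pc_in=pc_in, pc_out=pc_out,
                           pl_in=pl_in, pl_out=pl_out,
                           reach_in=reach_in, reach_out=reach_out)


def _top_set(values: np.ndarray, count: int, ascending: bool) -> np.ndarray:
    """Boolean mask of the ``count`` most central nodes.

    Ties break by node index (stable); for path lengths (``ascending``)
    smaller is more central and nodes with poor reach sort last.
    """
    v = values.copy().astype(float)
    key = v if ascending else -v
    order = np.lexsort((np.arange(v.size), key))
    mask = np.zeros(v.size, dtype=bool)
    mask[order[:count]] = True
    return mask


def hub_score_classify(t: CentralityTable, top_fraction: float = 1 / 3,
                       min_measures: int = 3, min_reach: float = 0.05) -> HubSet:
    """Hub-score criterion: top third on >= 3 of 4 measures, per profile.

    Path length ranks ascending (short = central); nodes reaching (reached
    by) fewer than ``min_reach`` of the graph get the worst path-length rank.
    A node is a hub when its in-profile or out-profile qualifies.
    """
    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must be in (0, 1)")
    if not (1 <= min_measures <= 4):
        raise ValueError("min_measures must be in 1..4")
    n = t.n_nodes
    count = int(np.floor(n * top_fraction))
    if count == 0:
        warnings.warn("fewer nodes than 1/top_fraction: no hubs definable")
    qualifies = np.zeros(n, dtype=bool)
    for direction in ("in", "out"):
        deg, btw, pc, pl = t.profile(direction)
        reach = t.reach_in if direction == "in" else t.reach_out
        pl_rank = pl.copy()
        if reach is not None:
            pl_rank[reach < min_reach] = np.inf
        hits = (_top_set(deg, count, False).astype(int)
                + _top_set(btw, count, False)
                + _top_set(pc, count, False)
                + _top_set(pl_rank, count, True))
        qualifies |= hits >= min_measures
    return HubSet(is_hub=qualifies, method="hub_score",
                  params={"top_fraction": top_fraction,
                          "min_measures": min_measures})


def kmeans_classify(t: CentralityTable, seed=None, min_reach: float = 0.05
                    ) -> HubSet:
    """k=2 k-means on z-scored centrality profiles; hub cluster = the one
    with the higher mean standardized degree. In/out profiles are clustered
    separately and combined with OR."""
    n = t.n_nodes
    if n < 4:
        raise ValueError("need at least 4 nodes")
    qualifies = np.zeros(n, dtype=bool)
    rng = np.random.default_rng(seed)
    for direction in ("in", "out"):
        deg, btw, pc, pl = t.profile(direction)
        reach = t.reach_in if direction == "in" else t.reach_out
        pl_feat = -pl.copy()  # negate: larger = more central
        bad = ~np.isfinite(pl_feat)
        if reach is not None:
            bad |= reach < min_reach
        pl_feat[bad] = np.min(pl_feat[~bad]) if (~bad).any() else 0.0
        feats = []
        for f in (deg, btw, pc, pl_feat):
            sd = f.std()
            if sd == 0:
                warnings.warn("zero-variance centrality feature dropped")
                continue
            feats.append((f - f.mean()) / sd)
        if not feats:
            continue
        Xf = np.column_stack(feats)
        km = KMeans(n_clusters=2, n_init=10,
                    random_state=int(rng.integers(2 ** 31)))
        lab = km.fit_predict(Xf)
        # cluster with the higher mean standardized degree is the hub cluster
        deg_z = (deg - deg.mean()) / (deg.std() if deg.std() else 1.0)
        hub_cluster = int(deg_z[lab == 1].mean() > deg_z[lab == 0].mean())
        qualifies |= lab == hub_cluster
    return HubSet(is_hub=qualifies, method="kmeans", params={"k": 2})


def hub_icn_test(h: HubSet, p: Partition, n_perm: int = 10000,
                 alpha: float = 0.05, seed=None) -> dict:
    """Per-module hub density against random relabelling of the same number
    of hubs across assigned nodes; two one-sided add-one p-values per module,
    Bonferroni over the module count."""
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    assigned = np.nonzero(p.assigned)[0]
    hub_flags = h.is_hub[assigned]
    n_hubs = int(hub_flags.sum())
    mods = p.module_ids
    K = mods.size
    sizes = np.array([p.members(int(m)).size for m in mods])
    obs = np.array([h.is_hub[p.members(int(m))].sum() / p.members(int(m)).size
                    for m in mods])
    ge = np.zeros(K)
    le = np.zeros(K)
    labels_assigned = p.labels[assigned]
    for _ in range(n_perm):
        perm = np.zeros(assigned.size, dtype=bool)
        perm[rng.choice(assigned.size, size=n_hubs, replace=False)] = True
        dens = np.array([perm[labels_assigned == m].sum() for m in mods]) / sizes
        ge += dens >= obs
        le += dens <= obs
    p_high = (1 + ge) / (1 + n_perm)
    p_low = (1 + le) / (1 + n_perm)
    thr = (alpha / 2) / K
    return {int(m): {"density": float(obs[k]), "p_high": float(p_high[k]),
                     "p_low": float(p_low[k]),
                     "significant": bool(p_high[k] <= thr or p_low[k] <= thr)}
            for k, m in enumerate(mods)}


def edge_class_counts(d: DifferenceMatrix, h: HubSet):
    """Counts of nonzero edges between hubs, hub-periphery, and periphery."""
    if d.n_nodes != h.is_hub.size:
        raise ValueError("difference matrix and hub set sizes differ")
    nz = d.values != 0
    hub = h.is_hub
    hub_hub = int(nz[np.ix_(hub, hub)].sum())
    per_per = int(nz[np.ix_(~hub, ~hub)].sum())
    hub_per = int(nz.sum() - hub_hub - per_per)
    return {"hub_hub": hub_hub, "hub_periphery": hub_per,
            "periphery_periphery": per_per}
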