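"""Core containers shared across the pipeline.

The two central objects are :class:`RoiTimeSeries` (a T x N matrix of mean
BOLD signal per region of interest) and :class:`Partition` (the assignment of
regions to intrinsic connectivity networks). Both are thin, validated wrappers
around numpy arrays with explicit node identifiers, so that every downstream
stage can check alignment instead of trusting positional order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Label used for nodes that could not be assigned to any module.
UNASSIGNED: int = -1


def _as_node_ids(node_ids, n: int) -> list[str]:
    if node_ids is None:
        return [f"roi{i:03d}" for i in range(n)]
    ids = [str(x) for x in node_ids]
    if len(ids) != n:
        raise ValueError(f"expected {n} node ids, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("node ids must be unique")
    return ids


@dataclass
class RoiTimeSeries:
    """Mean BOLD time series for a set of regions.

    Parameters
    ----------
    values : ndarray, shape (T, N)
        One row per acquired volume, one column per region.
    tr : float
        Repetition time (sampling interval) in seconds.
    run_labels : ndarray of shape (T,), optional
        Run/session identifier per row. Filters never mix rows across runs.
    node_ids : sequence of str, optional
        Region labels; generated as ``roi000 ...`` when omitted.
    """

    values: np.ndarray
    tr: float
    run_labels: np.ndarray = None
    node_ids: list[str] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (time x nodes) array")
        if np.isinf(self.values).any():
            raise ValueError("time series contain infinite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        T = self.values.shape[0]
        if self.run_labels is None:
            self.run_labels = np.zeros(T, dtype=int)
        else:
            self.run_labels = np.asarray(self.run_labels)
            if self.run_labels.shape != (T,):
                raise ValueError("run_labels must have one entry per row")
        self.node_ids = _as_node_ids(self.node_ids, self.values.shape[1])

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def runs(self):
        """Yield ``(run_label, row_index_array)`` in order of first appearance."""
        seen = []
        for lab in self.run_labels:
            if lab not in seen:
                seen.append(lab)
        for lab in seen:
            yield lab, np.nonzero(self.run_labels == lab)[0]

    def with_values(self, values: np.ndarray) -> "RoiTimeSeries":
        return RoiTimeSeries(values=np.asarray(values, dtype=float), tr=self.tr,
                             run_labels=self.run_labels.copy(),
                             node_ids=list(self.node_ids))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.node_ids)
        df.insert(0, "run", self.run_labels)
        return df


@dataclass
class TaskDesign:
    """Blocked task design: one row per modelled event.

    ``table`` has columns (session, condition, onset, duration) with onsets in
    seconds relative to the start of the session.
    """

    table: pd.DataFrame
    tr: float
    n_volumes: int
    conditions: tuple = ("emotion", "shape")

    def __post_init__(self):
        required = {"session", "condition", "onset", "duration"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        if len(self.table) and (self.table["onset"] < 0).any():
            raise ValueError("onsets must be non-negative")
        scan_s = self.n_volumes * self.tr
        if len(self.table):
            end = (self.table["onset"] + self.table["duration"]).max()
            if end > scan_s + 1e-9:
                raise ValueError(
                    f"design exceeds scan duration by {end - scan_s:.2f} s "
                    f"(scan {scan_s:.2f} s)")

    @property
    def sessions(self) -> list:
        return sorted(self.table["session"].unique()) if len(self.table) else []

    def session_events(self, session) -> pd.DataFrame:
        return self.table[self.table["session"] == session]

    @property
    def scan_duration_s(self) -> float:
        return self.n_volumes * self.tr


@dataclass
class Partition:
    """Node-to-module assignment with an explicit unassigned marker.

    ``labels[i] == UNASSIGNED`` marks a node excluded from every module-level
    statistic (the group consensus step produces such nodes when a region is
    isolated after thresholding or unstable across optimizer runs).
    """

    labels: np.ndarray
    node_ids: list[str] = None
    module_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        self.node_ids = _as_node_ids(self.node_ids, self.labels.size)
        for m in self.module_ids:
            self.module_names.setdefault(int(m), f"module{int(m)}")

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def module_ids(self) -> np.ndarray:
        """Sorted ids of non-empty modules (excluding UNASSIGNED)."""
        ids = np.unique(self.labels)
        return ids[ids != UNASSIGNED]

    @property
    def n_modules(self) -> int:
        return self.module_ids.size

    @property
    def assigned(self) -> np.ndarray:
        return self.labels != UNASSIGNED

    def members(self, module_id: int) -> np.ndarray:
        return np.nonzero(self.labels == module_id)[0]

    def relabel_canonical(self) -> "Partition":
        """Relabel modules 0..K-1 in order of first node appearance."""
        out = np.full_like(self.labels, UNASSIGNED)
        mapping: dict[int, int] = {}
        for i, lab in enumerate(self.labels):
            if lab == UNASSIGNED:
                continue
            if lab not in mapping:
                mapping[lab] = len(mapping)
            out[i] = mapping[lab]
        return Partition(labels=out, node_ids=list(self.node_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node_id": self.node_ids,
            "module_id": self.labels,
            "module_name": [self.module_names.get(int(l), "unassigned")
                            if l != UNASSIGNED else "unassigned"
                            for l in self.labels],
        })
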