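"""First-level GLM activation analysis and group ICN summaries.

A session-wise design matrix contains HRF-convolved condition regressors,
unconvolved motion regressors with their first temporal derivatives, and a
constant. OLS contrasts (emotion minus control) per region feed group
one-sample t-tests aggregated to module level with Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Partition, RoiTimeSeries, TaskDesign, UNASSIGNED
from .hrf import HRF, boxcar, convolve_hrf

__all__ = ["DesignMatrix", "ContrastResult", "build_design",
           "fit_first_level", "subject_contrast", "group_icn_activation"]


@dataclass
class DesignMatrix:
    """T x P design with named, role-tagged columns."""

    values: np.ndarray
    names: list[str]
    roles: list[str]  # condition | nuisance | constant

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.names) or len(self.names) != len(self.roles):
            raise ValueError("names/roles must match design columns")
        if self.roles.count("constant") < 1:
            raise ValueError("design needs a constant column")
        rank = np.linalg.matrix_rank(self.values)
        if rank < self.values.shape[1]:
            corr = np.corrcoef(self.values.T)
            pairs = [(self.names[i], self.names[j])
                     for i in range(len(self.names))
                     for j in range(i + 1, len(self.names))
                     if abs(corr[i, j]) > 1 - 1e-10]
            raise np.linalg.LinAlgError(
                f"design rank deficient (rank {rank} < {self.values.shape[1]}); "
                f"collinear columns: {pairs if pairs else 'non-pairwise dependency'}")

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def columns(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == role]

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(self.n_columns)
        for name, w in weights.items():
            if name not in self.names:
                raise KeyError(f"no design column named {name!r}")
            c[self.names.index(name)] = w
        return c


@dataclass
class ContrastResult:
    """Per-node contrast estimate with its t statistic."""

    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int


def build_design(design: TaskDesign, session, nuisance: np.ndarray = None,
                 hrf: HRF = HRF(), cue_handling: str = "merge",
                 cue_s: float = 3.0) -> DesignMatrix:
    """Design matrix for one session.

    Condition boxcars are sampled at the TR and convolved with the canonical
    HRF; motion columns and their first differences stay unconvolved; one
    constant column. ``cue_handling`` decides whether the cue period at the
    start of each block is merged into the block (default), modelled as its
    own regressor, or dropped.
    """
    if cue_handling not in ("merge", "separate", "ignore"):
        raise ValueError("cue_handling must be merge|separate|ignore")
    T = design.n_volumes
    events = design.session_events(session)
    cols, names, roles = [], [], []
    for cond in design.conditions:
        ev = events[events.condition == cond]
        onsets = ev["onset"].to_numpy(dtype=float)
        durations = ev["duration"].to_numpy(dtype=float)
        if cue_handling == "ignore":
            onsets = onsets + cue_s
            durations = durations - cue_s
        order = np.argsort(onsets)
        if np.any(onsets[order][1:] < (onsets + durations)[order][:-1] - 1e-9):
            raise ValueError(f"overlapping blocks for condition {cond!r}")
        box = boxcar(onsets, durations, design.tr, T)
        cols.append(convolve_hrf(box, hrf, design.tr))
        names.append(cond)
        roles.append("condition")
    if cue_handling == "separate" and len(events):
        box = boxcar(events["onset"].to_numpy(float),
                     np.full(len(events), cue_s), design.tr, T)
        cols.append(convolve_hrf(box, hrf, design.tr))
        names.append("cue")
        roles.append("condition")
    if nuisance is not None and np.size(nuisance):
        nuis = np.asarray(nuisance, dtype=float)
        if nuis.shape[0] != T:
            raise ValueError("nuisance rows must equal session volumes")
        deriv = np.vstack([np.zeros((1, nuis.shape[1])), np.diff(nuis, axis=0)])
        for j in range(nuis.shape[1]):
            cols.append(nuis[:, j]); names.append(f"motion{j+1}"); roles.append("nuisance")
        for j in range(nuis.shape[1]):
            cols.append(deriv[:, j]); names.append(f"dmotion{j+1}"); roles.append("nuisance")
    cols.append(np.ones(T)); names.append("constant"); roles.append("constant")
    return DesignMatrix(values=np.column_stack(cols), names=names, roles=roles)


def _ols(Y: np.ndarray, X: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = X.shape[0] - np.linalg.matrix_rank(X)
    sigma2 = (resid ** 2).sum(axis=0) / df
    return beta, sigma2, df


def fit_first_level(ts_or_values, X, contrast) -> ContrastResult:
    """OLS fit and t-test of a linear contrast of the coefficients.

    ``contrast`` may be a weight vector over columns or a ``{name: weight}``
    dict when ``X`` is a :class:`DesignMatrix`.
    """
    Y = ts_or_values.values if isinstance(ts_or_values, RoiTimeSeries) else np.asarray(ts_or_values, float)
    if isinstance(X, DesignMatrix):
        c = X.contrast_vector(contrast) if isinstance(contrast, dict) else np.asarray(contrast, float)
        Xv = X.values
    else:
        Xv = np.asarray(X, dtype=float)
        c = np.asarray(contrast, dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, sigma2, df = _ols(Y, Xv)
    xtx_inv = np.linalg.inv(Xv.T @ Xv)
    cvar = float(c @ xtx_inv @ c)
    cb = c @ beta
    if cvar == 0:  # zero contrast vector
        t = np.zeros_like(cb)
        p = np.ones_like(cb)
    else:
        se = np.sqrt(cvar * sigma2)
        t = np.divide(cb, se, out=np.zeros_like(cb), where=se > 0)
        p = 2 * stats.t.sf(np.abs(t), df)
    return ContrastResult(beta=cb, t=t, p=p, df=df)


def subject_contrast(ts: RoiTimeSeries, design: TaskDesign,
                     nuisance=None, hrf: HRF = HRF(),
                     contrast: dict = None,
                     session_weights=None) -> np.ndarray:
    """Per-node contrast value for one subject, averaged across sessions.

    Fits each session separately (its own drift-free design and constant) and
    combines session-wise contrast estimates with ``session_weights``
    (default: equal weights averaging the sessions).
    """
    contrast = contrast or {"emotion": 1.0, "shape": -1.0}
    sessions = design.sessions
    if session_weights is None:
        session_weights = np.full(len(sessions), 1.0 / len(sessions))
    vals = np.zeros(ts.n_nodes)
    for w, sess in zip(session_weights, sessions):
        rows = np.nonzero(ts.run_labels == sess)[0]
        nuis = None if nuisance is None else np.asarray(nuisance)[rows]
        X = build_design(design, sess, nuisance=nuis, hrf=hrf)
        res = fit_first_level(ts.values[rows], X, contrast)
        vals += w * res.beta
    return vals


def group_icn_activation(contrasts: np.ndarray, partition: Partition,
                         alpha: float = 0.05):
    """Module-level one-sample t-tests of subject contrast values.

    ``contrasts`` is (n_subjects, n_nodes). Per module the node-mean contrast
    per subject enters a two-sided one-sample t-test; p-values are multiplied
    by the number of modules (Bonferroni, capped at 1).
    """
    contrasts = np.asarray(contrasts, dtype=float)
    if contrasts.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if contrasts.shape[1] != partition.n_nodes:
        raise ValueError("contrast columns must match partition nodes")
    K = partition.n_modules
    out = {}
    for m in partition.module_ids:
        members = partition.members(int(m))
        if members.size == 0:
            warnings.warn(f"module {m} has no nodes; skipped")
            continue
        x = contrasts[:, members].mean(axis=1)
        mean = float(x.mean())
        se = float(x.std(ddof=1) / np.sqrt(x.size))
        if se == 0:
            t, p = (0.0, 1.0) if mean == 0 else (np.inf * np.sign(mean), 0.0)
        else:
            t = mean / se
            p = float(2 * stats.t.sf(abs(t), x.size - 1))
        out[int(m)] = {"mean": mean, "se": se, "t": float(t),
                       "p_bonferroni": min(p * K, 1.0)}
    return out
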