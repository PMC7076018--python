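"""Generalized psychophysiological interactions over all ordered ROI pairs.

For every seed region, a regression per target includes: one interaction
column per task condition (HRF-convolved product of the deconvolved seed
signal with the condition indicator), the seed BOLD time course, the
HRF-convolved condition regressors, unconvolved motion regressors with first
temporal derivatives, and a constant. Interaction coefficients per
(seed, target, condition, session) form the subject beta stack; a group
one-sample t-test on the condition contrast, Bonferroni-corrected over all
N(N-1) ordered pairs, yields the signed ternary difference matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import RoiTimeSeries, TaskDesign
from .glm import DesignMatrix, build_design
from .hrf import HRF, boxcar, convolve_hrf
from .prep import highpass_dct, ar1_coefficient

__all__ = ["Deconvolver", "deconvolve", "build_gppi_design",
           "fit_gppi_all_targets", "PpiBetaStack", "DifferenceMatrix",
           "run_gppi_subject", "difference_matrix",
           "bonferroni_edge_threshold"]


class Deconvolver:
    """Ridge-regularized estimate of the latent neural series behind BOLD.

    Solves ``min_c ||H B c - y||^2 + lam ||c||^2`` where ``H`` is the causal
    HRF convolution matrix and ``B`` an orthonormal discrete-cosine basis of
    the latent series; the estimate is ``n = B c``. The linear operator is
    precomputed once per (T, tr, HRF, lam).
    """

    def __init__(self, n: int, tr: float, hrf: HRF = HRF(),
                 regularization: float = 1.0):
        if regularization < 0:
            raise ValueError("regularization must be non-negative")
        self.n, self.tr, self.hrf, self.lam = n, tr, hrf, regularization
        k = hrf.kernel(tr)
        H = np.zeros((n, n))
        for i in range(min(len(k), n)):
            H += np.diag(np.full(n - i, k[i]), -i)
        t = np.arange(n)
        B = np.cos(np.pi * np.outer(t + 0.5, np.arange(n)) / n)
        B /= np.linalg.norm(B, axis=0)
        A = H @ B
        self._H = H
        self._M = B @ np.linalg.solve(A.T @ A + self.lam * np.eye(n), A.T)

    def __call__(self, bold: np.ndarray):
        """Returns (neural estimate, reconvolution R^2) for 1-D or 2-D input."""
        y = np.asarray(bold, dtype=float)
        if np.allclose(y.std(axis=0), 0):
            warnings.warn("zero-variance input: returning zero neural series")
            return np.zeros_like(y), 0.0
        neural = self._M @ y
        recon = self._H @ neural
        yc = y - y.mean(axis=0)
        ss_tot = np.sum(yc ** 2)
        ss_res = np.sum((y - recon) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return neural, float(r2)


def deconvolve(bold: np.ndarray, tr: float, hrf: HRF = HRF(),
               regularization: float = 1.0):
    """One-shot wrapper around :class:`Deconvolver`."""
    return Deconvolver(len(bold), tr, hrf, regularization)(bold)


def build_gppi_design(seed_ts: np.ndarray, design: TaskDesign, session,
                      nuisance: np.ndarray = None, hrf: HRF = HRF(),
                      deconvolver: Deconvolver | None = None,
                      use_deconvolution: bool = True,
                      regularization: float = 1.0) -> DesignMatrix:
    """Seed-specific generalized PPI design for one session.

    One interaction column per condition: the (deconvolved, unless disabled)
    seed series gated by the condition boxcar and re-convolved with the HRF.
    """
    if len(design.conditions) < 2:
        raise ValueError("generalized PPI requires the full condition set (>= 2)")
    T = design.n_volumes
    seed = np.asarray(seed_ts, dtype=float)
    if seed.shape != (T,):
        raise ValueError("seed series length must equal session volumes")
    base = build_design(design, session, nuisance=nuisance, hrf=hrf)
    if use_deconvolution:
        if deconvolver is None:
            deconvolver = Deconvolver(T, design.tr, hrf, regularization)
        neural, _ = deconvolver(seed)
    else:
        neural = seed
    events = design.session_events(session)
    cols, names, roles = [], [], []
    for cond in design.conditions:
        ev = events[events.condition == cond]
        box = boxcar(ev["onset"].to_numpy(float), ev["duration"].to_numpy(float),
                     design.tr, T)
        cols.append(convolve_hrf(neural * box, hrf, design.tr))
        names.append(f"ppi_{cond}")
        roles.append("ppi")
    cols.append(seed)
    names.append("seed")
    roles.append("seed")
    return DesignMatrix(
        values=np.column_stack(cols + [base.values]),
        names=names + base.names, roles=roles + base.roles)


def fit_gppi_all_targets(seed_index: int, Y: np.ndarray, X: DesignMatrix
                         ) -> dict[str, np.ndarray]:
    """OLS interaction betas for every target node (seed target is NaN).

    Returns ``{condition: per-target beta}`` for the PPI columns of ``X``.
    """
    Xv = X.values
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise np.linalg.LinAlgError("gPPI design is rank deficient")
    beta, *_ = np.linalg.lstsq(Xv, Y, rcond=None)
    out = {}
    for i, (name, role) in enumerate(zip(X.names, X.roles)):
        if role == "ppi":
            b = beta[i].astype(float)
            b[seed_index] = np.nan
            out[name.removeprefix("ppi_")] = b
    return out


@dataclass
class PpiBetaStack:
    """Interaction betas: (seed, target, condition, session); diagonal NaN."""

    betas: np.ndarray  # (N, N, n_conditions, n_sessions)
    conditions: tuple
    subject: str = ""

    def __post_init__(self):
        b = np.asarray(self.betas, dtype=float)
        if b.ndim != 4 or b.shape[0] != b.shape[1]:
            raise ValueError("betas must be (N, N, n_cond, n_sess)")
        if b.shape[2] != len(self.conditions):
            raise ValueError("condition axis mismatch")
        diag = np.arange(b.shape[0])
        b[diag, diag] = np.nan
        self.betas = b
        flat = b[~np.isnan(b)]
        if not np.all(np.isfinite(flat)):
            raise ValueError("non-finite off-diagonal betas")


@dataclass
class DifferenceMatrix:
    """Directed ternary matrix of significant task-evoked coupling changes."""

    values: np.ndarray  # int, {-1, 0, +1}, rows = seed, cols = target
    alpha: float = 0.05
    n_tests: int = None

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("difference matrix must be square")
        if not np.isin(v, (-1, 0, 1)).all():
            i, j = np.argwhere(~np.isin(v, (-1, 0, 1)))[0]
            raise ValueError(
                f"entry outside {{-1,0,1}} at row {int(i)}, column {int(j)}")
        v = v.astype(np.int8).copy()
        np.fill_diagonal(v, 0)
        self.values = v
        n = v.shape[0]
        if self.n_tests is None:
            self.n_tests = n * (n - 1)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def bonferroni_edge_threshold(n_nodes: int, alpha: float = 0.05):
    """(number of ordered pairs, per-edge p threshold) for N nodes."""
    n_tests = n_nodes * (n_nodes - 1)
    return n_tests, alpha / n_tests


def run_gppi_subject(ts: RoiTimeSeries, design: TaskDesign,
                     nuisance: np.ndarray = None, hrf: HRF = HRF(),
                     highpass_s: float = 200.0, use_deconvolution: bool = True,
                     regularization: float = 1.0, subject: str = "") -> PpiBetaStack:
    """Full seed-wise gPPI pass for one subject.

    Per session: high-pass filter, estimate a session-pooled AR(1)
    coefficient from the base-model residuals, adjust seed series for the
    effects of interest (condition columns), then for every seed build the
    interaction design, apply the quasi-differencing prewhitening transform to
    data and design, and fit all targets at once. Normal equations are batched
    across seeds.
    """
    N = ts.n_nodes
    conditions = design.conditions
    sessions = design.sessions
    betas = np.full((N, N, len(conditions), len(sessions)), np.nan)
    ts_f = highpass_dct(ts, highpass_s)
    deconv = None
    for s_idx, sess in enumerate(sessions):
        rows = np.nonzero(ts.run_labels == sess)[0]
        Y = ts_f.values[rows]
        T = rows.size
        nuis = None if nuisance is None else np.asarray(nuisance)[rows]
        base = build_design(design, sess, nuisance=nuis, hrf=hrf)
        X0 = base.values
        # pooled AR(1) estimate from base-model residuals
        b0, *_ = np.linalg.lstsq(X0, Y, rcond=None)
        resid = Y - X0 @ b0
        rho = float(ar1_coefficient(resid).mean())
        # seeds adjusted for effects of interest (conditions): fitted
        # condition effects + residuals
        cond_cols = base.columns("condition")
        Y_adj = X0[:, cond_cols] @ b0[cond_cols] + resid
        if use_deconvolution and deconv is None:
            deconv = Deconvolver(T, design.tr, hrf, regularization)
        # per-seed designs, fully vectorized (identical to build_gppi_design,
        # which remains the reference path and is tested against this one)
        if use_deconvolution:
            neural = deconv._M @ Y_adj                     # (T, N)
        else:
            neural = Y_adj
        k = hrf.kernel(design.tr)
        H = np.zeros((T, T))
        for i in range(min(len(k), T)):
            H += np.diag(np.full(T - i, k[i]), -i)
        events = design.session_events(sess)
        n_cond = len(conditions)
        P = n_cond + 1 + X0.shape[1]
        X_all = np.empty((N, T, P))
        ppi_cols = list(range(n_cond))
        ppi_conds = list(conditions)
        for ci, cond in enumerate(conditions):
            ev = events[events.condition == cond]
            box = boxcar(ev["onset"].to_numpy(float),
                         ev["duration"].to_numpy(float), design.tr, T)
            X_all[:, :, ci] = (H @ (neural * box[:, None])).T
        X_all[:, :, n_cond] = Y_adj.T                      # seed column
        X_all[:, :, n_cond + 1:] = X0[None, :, :]
        # prewhitening: quasi-difference data and every design with rho
        Yw = Y[1:] - rho * Y[:-1]
        Xw = X_all[:, 1:, :] - rho * X_all[:, :-1, :]
        # batched OLS via normal equations
        XtX = np.einsum("ntp,ntq->npq", Xw, Xw)
        XtY = np.einsum("ntp,tm->npm", Xw, Yw)
        coef = np.linalg.solve(XtX, XtY)                  # (N, P, N_targets)
        for ci, cond in enumerate(conditions):
            col = ppi_cols[ppi_conds.index(cond)]
            betas[:, :, ci, s_idx] = coef[:, col, :]
    return PpiBetaStack(betas=betas, conditions=tuple(conditions),
                        subject=subject)


def difference_matrix(stacks: list[PpiBetaStack],
                      condition_weights: dict[str, float] = None,
                      session_weights=None, alpha: float = 0.05
                      ) -> DifferenceMatrix:
    """Group-level signed ternary matrix from subject beta stacks.

    Per subject and ordered pair, interaction betas are combined with the
    condition contrast (default emotion - shape) and averaged across sessions;
    a two-sided one-sample t-test across subjects is thresholded at
    ``alpha / (N(N-1))`` and the sign of significant means is recorded.
    """
    if len(stacks) < 3:
        raise ValueError("need at least 3 subjects")
    conds = stacks[0].conditions
    N = stacks[0].betas.shape[0]
    for s in stacks[1:]:
        if s.betas.shape != stacks[0].betas.shape or s.conditions != conds:
            raise ValueError("beta stacks are not aligned")
    condition_weights = condition_weights or {conds[0]: 1.0, conds[1]: -1.0}
    cw = np.array([condition_weights.get(c, 0.0) for c in conds])
    n_sess = stacks[0].betas.shape[3]
    sw = (np.full(n_sess, 1.0 / n_sess) if session_weights is None
          else np.asarray(session_weights, dtype=float))
    vals = np.stack([
        np.tensordot(np.tensordot(s.betas, cw, axes=([2], [0])), sw,
                     axes=([2], [0]))
        for s in stacks])                                   # (S, N, N)
    n = vals.shape[0]
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    n_tests, thr = bonferroni_edge_threshold(N, alpha)
    p = 2 * stats.t.sf(np.abs(t), n - 1)
    out = np.zeros((N, N), dtype=np.int8)
    sig = p < thr
    sig &= ~np.isnan(mean)
    out[sig & (mean > 0)] = 1
    out[sig & (mean < 0)] = -1
    np.fill_diagonal(out, 0)
    return DifferenceMatrix(values=out, alpha=alpha, n_tests=n_tests)
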