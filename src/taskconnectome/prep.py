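"""Temporal preprocessing of ROI time series.

Resting data are band-pass filtered (0.01-0.1 Hz) before connectivity
estimation; task data are high-pass filtered (200 s cutoff), prewhitened with
an AR(1) model, and adjusted for the effects of interest before serving as
seed time courses in interaction models.

All filters here are realized as projections onto a discrete-cosine basis,
per run, so that their behaviour is exact linear algebra: filtering a
concatenated series equals concatenating per-run filtered series, and the
variance removed from any input is exactly the squared norm of its projection
onto the removed subspace.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import RoiTimeSeries

__all__ = [
    "dct_basis", "bandpass", "highpass_dct", "prewhiten_ar1",
    "adjust_for_effects",
]


def dct_basis(n: int, n_components: int, include_trend: bool = False) -> np.ndarray:
    """Orthonormal DCT-II style cosine basis.

    Column ``k`` (1-based over the cosine part) is
    ``cos(pi * k * (t + 0.5) / n)``; its period is ``2 n / k`` samples, so the
    corresponding frequency at sampling interval ``tr`` is ``k / (2 n tr)``.
    With ``include_trend`` a centered linear ramp is prepended, which captures
    scanner drift exactly.
    """
    if n_components < 0 or n_components >= n:
        raise ValueError("need 0 <= n_components < n")
    t = np.arange(n)
    cols = []
    if include_trend:
        ramp = t - t.mean()
        cols.append(ramp / np.linalg.norm(ramp))
    for k in range(1, n_components + 1):
        c = np.cos(np.pi * k * (t + 0.5) / n)
        cols.append(c / np.linalg.norm(c))
    if not cols:
        return np.empty((n, 0))
    basis = np.column_stack(cols)
    # Gram-Schmidt residual pass: the ramp is not exactly orthogonal to cosines
    q, _ = np.linalg.qr(basis)
    return q


def _per_run(ts: RoiTimeSeries, fn) -> RoiTimeSeries:
    out = np.empty_like(ts.values)
    for _, idx in ts.runs():
        out[idx] = fn(ts.values[idx])
    return ts.with_values(out)


def bandpass(ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.1) -> RoiTimeSeries:
    """Retain fluctuations with frequencies in ``[low_hz, high_hz]``.

    Applied independently per run. The output is the projection of each
    (demeaned) run onto the cosine components whose frequencies fall inside
    the passband, so DC and drift are removed by construction.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"passband [{low_hz}, {high_hz}] Hz outside (0, Nyquist={nyquist:.4f}) range")

    def _filter(x):
        n = x.shape[0]
        k = np.arange(1, n)
        freqs = k / (2.0 * n * ts.tr)
        keep = k[(freqs >= low_hz) & (freqs <= high_hz)]
        if keep.size == 0:
            warnings.warn("passband contains no basis component; returning zeros")
            return np.zeros_like(x)
        t = np.arange(n)
        basis = np.column_stack(
            [np.cos(np.pi * kk * (t + 0.5) / n) for kk in keep])
        basis /= np.linalg.norm(basis, axis=0)
        xc = x - x.mean(axis=0)
        return basis @ (basis.T @ xc)

    return _per_run(ts, _filter)


def n_highpass_components(n: int, tr: float, cutoff_s: float) -> int:
    """Number of cosine components with period longer than ``cutoff_s``."""
    return int(np.floor(2.0 * n * tr / cutoff_s))


def highpass_dct(ts: RoiTimeSeries, cutoff_s: float = 200.0) -> RoiTimeSeries:
    """Remove slow drifts with periods longer than ``cutoff_s`` seconds.

    Residualizes each run against mean, linear trend, and the
    ``floor(2 T tr / cutoff_s)`` slowest cosine components (the standard
    discrete-cosine high-pass used in first-level task models).
    """
    if cutoff_s <= 2 * ts.tr:
        raise ValueError("cutoff_s must exceed twice the sampling interval")

    def _filter(x):
        n = x.shape[0]
        k = n_highpass_components(n, ts.tr, cutoff_s)
        if k == 0 and n < 3:
            warnings.warn("run too short for any high-pass component; returning input")
            return x.copy()
        basis = dct_basis(n, min(k, n - 2), include_trend=True)
        xc = x - x.mean(axis=0)
        return xc - basis @ (basis.T @ xc)

    return _per_run(ts, _filter)


def _check_full_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via the null space
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        null = vt[s < s.max() * max(X.shape) * np.finfo(float).eps * 10]
        if null.size == 0:
            null = vt[-1:]
        cols = sorted(set(np.nonzero(np.abs(null) > 1e-8)[1].tolist()))
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {cols}")


def ar1_coefficient(resid: np.ndarray) -> np.ndarray:
    """Lag-1 autocorrelation of each residual column."""
    r = np.atleast_2d(resid.T).T
    r = r - r.mean(axis=0)
    num = np.sum(r[1:] * r[:-1], axis=0)
    den = np.sum(r * r, axis=0)
    rho = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return np.clip(rho, -0.999, 0.999)


def prewhiten_ar1(ts: RoiTimeSeries, design: np.ndarray, pool: bool = False):
    """Single-pass AR(1) prewhitening (Cochrane-Orcutt).

    Fits an initial OLS of every column on ``design``, estimates the lag-1
    autocorrelation rho of the residuals, and applies the quasi-differencing
    transform ``y_t - rho * y_{t-1}`` to data and design, dropping the first
    row of each run. With ``pool=True`` a single rho (the across-column mean)
    is used and the returned design is 2-D; otherwise rho is per column and
    the design gains a leading per-column axis.

    Returns
    -------
    (whitened RoiTimeSeries, whitened design, rho)
    """
    X = np.asarray(design, dtype=float)
    Y = ts.values
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design rows must match time points")
    _check_full_rank(X)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    # estimate rho within runs so run boundaries never mix
    num = np.zeros(Y.shape[1])
    den = np.zeros(Y.shape[1])
    for _, idx in ts.runs():
        r = resid[idx] - resid[idx].mean(axis=0)
        num += np.sum(r[1:] * r[:-1], axis=0)
        den += np.sum(r * r, axis=0)
    rho = np.clip(np.divide(num, den, out=np.zeros_like(num), where=den > 0),
                  -0.999, 0.999)
    if pool:
        rho = np.full(Y.shape[1], float(rho.mean()))

    keep_rows = []
    segments = []
    for _, idx in ts.runs():
        keep_rows.append(idx[1:])
        segments.append(idx)
    keep = np.concatenate(keep_rows)

    def _quasi_diff(arr, r):
        # arr: (T, ...) -> rows ``idx[1:]`` of arr - r * lagged arr, per run
        parts = []
        for idx in segments:
            parts.append(arr[idx[1:]] - r * arr[idx[:-1]])
        return np.concatenate(parts, axis=0)

    if pool:
        r0 = rho[0]
        Yw = _quasi_diff(Y, r0)
        Xw = _quasi_diff(X, r0)
    else:
        Yw = np.empty((keep.size, Y.shape[1]))
        Xw = np.empty((Y.shape[1], keep.size, X.shape[1]))
        for j in range(Y.shape[1]):
            Yw[:, j] = _quasi_diff(Y[:, [j]], rho[j])[:, 0]
            Xw[j] = _quasi_diff(X, rho[j])
    ts_w = RoiTimeSeries(values=Yw, tr=ts.tr, run_labels=ts.run_labels[keep],
                         node_ids=list(ts.node_ids))
    return ts_w, Xw, rho


def adjust_for_effects(ts: RoiTimeSeries, design: np.ndarray,
                       effects_of_interest) -> RoiTimeSeries:
    """Remove the nuisance partition of a fitted design from the data.

    The output is ``X[:, interest] @ beta[interest] + residuals``: the data
    with the fitted contribution of every column *not* of interest subtracted.
    This mirrors adjusting a seed time course for the effects-of-interest
    F-contrast before it enters an interaction model.
    """
    X = np.asarray(design, dtype=float)
    if X.shape[0] != ts.n_timepoints:
        raise ValueError("design rows must match time points")
    _check_full_rank(X)
    interest = np.asarray(effects_of_interest, dtype=int)
    if interest.size and (interest.min() < 0 or interest.max() >= X.shape[1]):
        raise ValueError("effects_of_interest outside design columns")
    if interest.size == 0:
        warnings.warn("empty effects-of-interest set: returning pure residuals")
    beta, *_ = np.linalg.lstsq(X, ts.values, rcond=None)
    fitted_interest = X[:, interest] @ beta[interest] if interest.size else 0.0
    resid = ts.values - X @ beta
    return ts.with_values(fitted_interest + resid)
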