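"""Canonical double-gamma hemodynamic response function.

The kernel is the difference of two gamma densities: a response peaking at
``peak_delay`` seconds and an undershoot peaking at ``undershoot_delay``
seconds, scaled down by ``peak_undershoot_ratio``. Shapes are chosen so the
gamma modes sit exactly at the stated delays (shape = delay/dispersion + 1).
The kernel is truncated at ``length`` seconds, sampled at the repetition time,
and normalized to a unit peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HRF:
    """Parameters of the canonical double-gamma impulse response."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_undershoot_ratio: float = 6.0
    length: float = 32.0
    dispersion: float = 1.0

    def __post_init__(self):
        if self.peak_delay <= 0 or self.undershoot_delay <= self.peak_delay:
            raise ValueError("need 0 < peak_delay < undershoot_delay")
        if self.peak_undershoot_ratio <= 0 or self.length <= 0:
            raise ValueError("ratio and length must be positive")

    def kernel(self, tr: float) -> np.ndarray:
        """Sampled kernel at resolution ``tr``; positive integral, unit peak."""
        t = np.arange(0, self.length, tr)
        d = self.dispersion
        peak = stats.gamma.pdf(t, a=self.peak_delay / d + 1, scale=d)
        under = stats.gamma.pdf(t, a=self.undershoot_delay / d + 1, scale=d)
        h = peak - under / self.peak_undershoot_ratio
        if h.sum() <= 0:
            raise ValueError("kernel does not integrate to a positive value")
        return h / h.max()


def convolve_hrf(signal: np.ndarray, hrf: HRF, tr: float) -> np.ndarray:
    """Causal convolution of a (possibly multi-column) signal with the HRF,
    truncated to the input length."""
    k = hrf.kernel(tr)
    x = np.atleast_2d(np.asarray(signal, dtype=float).T).T
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = np.convolve(x[:, j], k)[: x.shape[0]]
    return out[:, 0] if np.ndim(signal) == 1 else out


def boxcar(onsets, durations, tr: float, n_volumes: int) -> np.ndarray:
    """Condition indicator sampled at volume acquisition times ``i * tr``."""
    t = np.arange(n_volumes) * tr
    box = np.zeros(n_volumes)
    for onset, dur in zip(np.atleast_1d(onsets), np.atleast_1d(durations)):
        box[(t >= onset) & (t < onset + dur)] = 1.0
    return box
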