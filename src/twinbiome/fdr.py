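"""Storey q-values with a smoother estimate of the null proportion pi0."""

from __future__ import annotations

import numpy as np


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Smoother estimate of the proportion of true nulls.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a grid,
    a cubic polynomial smoother is fit, and the fit is read off at the
    largest lambda; the estimate is clamped into (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0s = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    if np.all(pi0s == 0):
        return 1.0 / m
    coef = np.polyfit(lambdas, pi0s, deg=3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return min(1.0, max(pi0, 1.0 / m))


def qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; with ``pi0=1`` these equal Benjamini-Hochberg
    adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = estimate_pi0(p) if m >= 20 else 1.0
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pi0 * m * p[i] / rank)
        q[i] = prev
    return q
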