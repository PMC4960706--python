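"""Shared statistical primitives: BH adjustment and empirical-Bayes variance moderation.

The variance moderation follows the classic moment-matching scheme for a
scaled-inverse-chi-square prior on gene-wise variances: observed log
variances are location-corrected by digamma terms, the prior degrees of
freedom d0 come from inverting the trigamma function on the excess
variance of those residuals, and the prior scale s0^2 from their mean.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, polygamma


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR adjustment; returns adjusted p-values in input order.

    Raises ValueError on entries outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma_inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * abs(y):
            break
    return float(y)


def estimate_variance_prior(s2, df):
    """Estimate (d0, s0_sq) of the inverse-chi-square variance prior.

    Parameters are the per-gene residual variances ``s2`` with residual
    degrees of freedom ``df``.  Genes with non-positive variance or zero
    df are excluded from estimation.  Returns ``(d0, s0_sq)`` where d0
    may be ``inf`` (all variances pooled to s0_sq).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two genes with positive variance and df")
    s2u, dfu = s2[ok], df[ok]
    e = np.log(s2u) - digamma(dfu / 2.0) + np.log(dfu / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    excess = evar - np.mean(polygamma(1, dfu / 2.0))
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def moderate_variances(s2, df, d0: float, s0_sq: float) -> np.ndarray:
    """Posterior (shrunken) variances under the estimated prior."""
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    if d0 == 0:
        return s2.copy()
    return (d0 * s0_sq + df * s2) / (d0 + df)
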