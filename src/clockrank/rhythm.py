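"""Fixed-period cosinor test for transcript rhythmicity.

A deliberately simple stand-in for nonparametric rhythm detectors such as
JTK_cycle: each gene's time course is fit with a single cosine/sine pair at a
fixed period (default 24 h) and compared against a constant model with an
F-test.  Smaller p-values indicate more robust cycling.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: lower clamp applied to p-values so that -log10 products stay finite
P_VALUE_FLOOR = 1e-300

#: minimum number of time points accepted by the test
MIN_TIMEPOINTS = 8


def cosinor_design(times_h: np.ndarray, period_h: float = 24.0) -> np.ndarray:
    """Design matrix [1, cos(wt), sin(wt)] for the fixed-period cosinor fit."""
    t = np.asarray(times_h, dtype=float)
    w = 2.0 * np.pi / float(period_h)
    return np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])


def cosinor_pvalues(
    values: np.ndarray, times_h: np.ndarray, period_h: float = 24.0
) -> np.ndarray:
    """Cosinor F-test p-values for many genes at once.

    Parameters
    ----------
    values
        Expression matrix of shape ``(n_genes, n_times)``; rows are genes.
    times_h
        Sampling times in hours, length ``n_times``.
    period_h
        Fixed period of the fitted cosine, in hours.

    Returns
    -------
    Array of p-values in ``[P_VALUE_FLOOR, 1]``, one per gene.  Constant
    series yield 1.0 (no evidence of rhythm, by convention), perfect cosine
    fits are clamped at ``P_VALUE_FLOOR``.
    """
    y = np.atleast_2d(np.asarray(values, dtype=float))
    t = np.asarray(times_h, dtype=float)
    n_t = t.size
    if y.shape[1] != n_t:
        raise ValueError(
            f"values have {y.shape[1]} columns but {n_t} times were given"
        )
    if n_t < MIN_TIMEPOINTS:
        raise ValueError(f"need at least {MIN_TIMEPOINTS} time points, got {n_t}")
    if not np.all(np.isfinite(y)):
        raise ValueError("expression values must be finite")

    X = cosinor_design(t, period_h)
    # one shared least-squares solve for all genes
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    resid = y.T - X @ beta
    rss1 = np.sum(resid**2, axis=0)
    rss0 = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    df2 = n_t - 3

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss0 - rss1) / 2.0) / (rss1 / df2)
        p = stats.f.sf(f_stat, 2, df2)

    p = np.where(rss0 == 0.0, 1.0, p)          # constant series: no evidence
    p = np.where((rss1 == 0.0) & (rss0 > 0.0), 0.0, p)  # perfect fit
    return np.clip(p, P_VALUE_FLOOR, 1.0)


def cosinor_pvalue(series, times_h, period_h: float = 24.0) -> float:
    """One-gene convenience wrapper around :func:`cosinor_pvalues`."""
    return float(cosinor_pvalues(np.asarray(series, dtype=float)[None, :], times_h, period_h)[0])
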