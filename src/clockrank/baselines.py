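"""Comparison rankers: Gaussian and kernel-density ("flexible") naive Bayes.

Both classifiers score the same five feature columns used by the evidence
factors, treat the exemplar genes as the positive class and every other gene
as nonclock, and rank genes by the posterior probability of clock membership.
A feature that is missing for a gene is skipped in its likelihood product,
mirroring the EF = 1 neutrality of the evidence-factor method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

NB_FEATURES = ["m_cyc", "m_dist", "m_int", "ubiquity_flag", "homology_flag"]

#: relative variance floor applied per feature (fraction of overall variance)
VARIANCE_FLOOR_FRACTION = 1e-9
_ABS_VAR_FLOOR = 1e-12


@dataclass
class NBModel:
    kind: str  # "gaussian" | "kernel"
    features: list[str]
    log_prior_clock: float
    log_prior_nonclock: float
    # gaussian: feature -> {class: (mean, sd)}; kernel: feature -> {class: (samples, bandwidth)}
    params: dict = field(repr=False, default_factory=dict)


def _class_split(table: pd.DataFrame, exemplars: Sequence[str]) -> np.ndarray:
    is_ex = table["gene_id"].isin(set(exemplars)).to_numpy()
    if is_ex.sum() < 2:
        raise ValueError("need at least 2 exemplar genes present in the feature table")
    return is_ex


def _priors(is_ex: np.ndarray) -> tuple[float, float]:
    p = is_ex.mean()
    return float(np.log(p)), float(np.log1p(-p))


def fit_gaussian_nb(
    table: pd.DataFrame, exemplars: Sequence[str], features: Sequence[str] = NB_FEATURES
) -> NBModel:
    """Per-class per-feature mean/SD from the available (non-missing) values.

    Variances are floored at ``VARIANCE_FLOOR_FRACTION`` times the overall
    feature variance so degenerate (constant) features cannot produce
    infinite densities; a class with no usable values drops the feature for
    that model with a warning.
    """
    is_ex = _class_split(table, exemplars)
    lp_c, lp_nc = _priors(is_ex)
    params: dict = {}
    for feat in features:
        v = table[feat].to_numpy(dtype=float)
        overall_var = np.nanvar(v)
        floor = max(VARIANCE_FLOOR_FRACTION * overall_var, _ABS_VAR_FLOOR)
        per_class = {}
        ok = True
        for label, mask in (("clock", is_ex), ("nonclock", ~is_ex)):
            x = v[mask]
            x = x[~np.isnan(x)]
            if x.size == 0:
                logger.warning("feature %s has no usable %s values; ignored", feat, label)
                ok = False
                break
            var = max(np.var(x), floor)
            per_class[label] = (float(np.mean(x)), float(np.sqrt(var)))
        if ok:
            params[feat] = per_class
    return NBModel("gaussian", list(params), lp_c, lp_nc, params)


def silverman_bandwidth(x: np.ndarray, fallback_sd: float) -> float:
    """1.06 * min(SD, IQR/1.34) * n^(-1/5); degenerate samples fall back to
    the overall feature SD (or a small positive constant)."""
    n = x.size
    if n >= 2:
        sd = np.std(x, ddof=1)
        q75, q25 = np.percentile(x, [75, 25])
        iqr = q75 - q25
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        h = 1.06 * spread * n ** (-0.2)
        if h > 0 and np.isfinite(h):
            return float(h)
    if fallback_sd > 0:
        return float(fallback_sd)
    return 1e-6


def fit_kernel_nb(
    table: pd.DataFrame, exemplars: Sequence[str], features: Sequence[str] = NB_FEATURES
) -> NBModel:
    """Gaussian kernel density per class and feature with a Silverman-type
    bandwidth heuristic; a single-sample class falls back to the overall
    feature SD as bandwidth."""
    is_ex = _class_split(table, exemplars)
    lp_c, lp_nc = _priors(is_ex)
    params: dict = {}
    for feat in features:
        v = table[feat].to_numpy(dtype=float)
        overall = v[~np.isnan(v)]
        fallback_sd = float(np.std(overall)) if overall.size else 0.0
        per_class = {}
        ok = True
        for label, mask in (("clock", is_ex), ("nonclock", ~is_ex)):
            x = v[mask]
            x = x[~np.isnan(x)]
            if x.size == 0:
                logger.warning("feature %s has no usable %s values; ignored", feat, label)
                ok = False
                break
            per_class[label] = (x.copy(), silverman_bandwidth(x, fallback_sd))
        if ok:
            params[feat] = per_class
    return NBModel("kernel", list(params), lp_c, lp_nc, params)


def _gaussian_logpdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    z = (x - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


def _kde_logpdf(x: np.ndarray, samples: np.ndarray, h: float) -> np.ndarray:
    z = (x[:, None] - samples[None, :]) / h
    return logsumexp(-0.5 * z * z, axis=1) - np.log(samples.size * h) - 0.5 * np.log(2.0 * np.pi)


def kernel_logpdf(model: NBModel, feature: str, label: str, x) -> np.ndarray:
    """Pointwise log density of one fitted class-conditional kernel model."""
    samples, h = model.params[feature][label]
    return _kde_logpdf(np.atleast_1d(np.asarray(x, dtype=float)), samples, h)


def nb_posterior(model: NBModel, table: pd.DataFrame) -> pd.Series:
    """P(clock | features) per gene, with missing features skipped."""
    n = len(table)
    log_c = np.full(n, model.log_prior_clock)
    log_nc = np.full(n, model.log_prior_nonclock)
    for feat in model.features:
        v = table[feat].to_numpy(dtype=float)
        present = ~np.isnan(v)
        if not present.any():
            continue
        x = v[present]
        if model.kind == "gaussian":
            (mu_c, sd_c) = model.params[feat]["clock"]
            (mu_nc, sd_nc) = model.params[feat]["nonclock"]
            lc = _gaussian_logpdf(x, mu_c, sd_c)
            lnc = _gaussian_logpdf(x, mu_nc, sd_nc)
        else:
            s_c, h_c = model.params[feat]["clock"]
            s_nc, h_nc = model.params[feat]["nonclock"]
            lc = _kde_logpdf(x, s_c, h_c)
            lnc = _kde_logpdf(x, s_nc, h_nc)
        log_c[present] += lc
        log_nc[present] += lnc
    # P(clock|x) = 1 / (1 + exp(log_nc - log_c))
    post = 1.0 / (1.0 + np.exp(np.clip(log_nc - log_c, -700, 700)))
    return pd.Series(post, index=pd.Index(table["gene_id"], name="gene_id"), name="posterior")


def nb_rank(model: NBModel, table: pd.DataFrame) -> pd.DataFrame:
    """Genes in descending posterior-probability order (ties: ascending id)."""
    post = nb_posterior(model, table)
    out = post.reset_index()
    out = out.sort_values(
        ["posterior", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
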