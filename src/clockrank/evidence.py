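"""Circadian evidence factors: ECDF tail-ratio scoring and gene ranking.

For one feature with metric value m, the evidence factor is

    EF(m) = P(M >= m' | clock) / P(M >= m' | nonclock),

with both tail probabilities taken from empirical survival functions — the
clock one over the exemplar genes, the nonclock one over every other gene —
and m' = min(m, exemplar maximum): values beyond the largest exemplar value
receive the same evidence as that maximum.  Boolean features use the standard
Bayes-factor ratio of class frequencies.  Under conditional independence the
combined evidence factor is the product over features, and multiplying by the
prior odds of clock membership yields posterior odds.  A missing feature is
neutral: its evidence factor is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: FeatureTable column -> output EF column
CONTINUOUS_FEATURES = {"m_cyc": "ef_cycling", "m_dist": "ef_disturbance", "m_int": "ef_interaction"}
BOOLEAN_FEATURES = {"ubiquity_flag": "ef_ubiquity", "homology_flag": "ef_homology"}
EF_COLUMNS = list(CONTINUOUS_FEATURES.values()) + list(BOOLEAN_FEATURES.values())


@dataclass(frozen=True)
class RankingConfig:
    """Knobs that affect reported odds but never the ranking itself.

    ``prior_odds`` defaults to n_exemplar / (n_universe - n_exemplar).
    """

    prior_odds: float | None = None

    def __post_init__(self) -> None:
        if self.prior_odds is not None and self.prior_odds <= 0:
            raise ValueError("prior odds must be positive")


class ClassConditionalECDF:
    """Empirical survival function S(m) = (# class values >= m)/n for one metric."""

    def __init__(self, values: Iterable[float], label: str = ""):
        vals = np.asarray(list(values), dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"empty sample for class ECDF {label!r}")
        self.values = np.sort(vals)
        self.n = int(vals.size)
        self.max = float(self.values[-1])
        self.label = label

    def tail_probability(self, m):
        """S(m) with the closed (>=) tail convention; vectorised over m."""
        m = np.asarray(m, dtype=float)
        count = self.n - np.searchsorted(self.values, m, side="left")
        out = count / self.n
        return float(out) if out.ndim == 0 else out


def tail_probability(m: float, ecdf: ClassConditionalECDF) -> float:
    return float(ecdf.tail_probability(m))


def feature_evidence_factor(
    m, clock_ecdf: ClassConditionalECDF, nonclock_ecdf: ClassConditionalECDF
):
    """EF = S_clock(m') / S_nonclock(m') with m' = min(m, exemplar max).

    Missing m gives EF = 1.  When no nonclock value reaches m' the
    denominator is floored at 1/(n_nonclock + 1) to keep the factor finite.
    """
    m = np.asarray(m, dtype=float)
    missing = np.isnan(m)
    m_cap = np.minimum(np.where(missing, clock_ecdf.max, m), clock_ecdf.max)
    s_clock = clock_ecdf.tail_probability(m_cap)
    s_non = nonclock_ecdf.tail_probability(m_cap)
    s_non = np.where(s_non == 0.0, 1.0 / (nonclock_ecdf.n + 1), s_non)
    ef = np.where(missing, 1.0, s_clock / s_non)
    return float(ef) if ef.ndim == 0 else ef


def boolean_bayes_factor(flag, clock_fraction_true: float, nonclock_fraction_true: float):
    """Standard Bayes factor for a Boolean feature; missing flag -> 1.

    The class fractions are estimated by the caller (see
    :func:`estimate_class_fractions`, which applies Laplace +1/+2 smoothing).
    """
    for f in (clock_fraction_true, nonclock_fraction_true):
        if not 0.0 <= f <= 1.0:
            raise ValueError("class fractions must lie in [0, 1]")
    flag = np.asarray(flag, dtype=float)
    missing = np.isnan(flag)
    ef_true = clock_fraction_true / nonclock_fraction_true
    ef_false = (1.0 - clock_fraction_true) / (1.0 - nonclock_fraction_true)
    ef = np.where(missing, 1.0, np.where(flag != 0, ef_true, ef_false))
    return float(ef) if ef.ndim == 0 else ef


def estimate_class_fractions(flags: pd.Series, is_exemplar: np.ndarray) -> tuple[float, float]:
    """Laplace-smoothed ((k+1)/(n+2)) fraction of true flags per class."""
    v = flags.to_numpy(dtype=float)
    out = []
    for mask in (is_exemplar, ~is_exemplar):
        x = v[mask]
        x = x[~np.isnan(x)]
        out.append((np.sum(x != 0) + 1.0) / (x.size + 2.0))
    return out[0], out[1]


def combined_evidence(per_feature_efs: Iterable[float]) -> float:
    """Product of per-feature EFs, accumulated in log space."""
    efs = np.asarray(list(per_feature_efs), dtype=float)
    if np.any(efs <= 0):
        raise ValueError("evidence factors must be positive")
    return float(np.exp(np.sum(np.log(efs))))


def posterior_odds(ef_total: float, prior_odds: float) -> float:
    """Posterior odds of clock membership = prior odds x combined EF."""
    if prior_odds <= 0:
        raise ValueError("prior odds must be positive")
    return prior_odds * ef_total


def _usable_exemplars(table: pd.DataFrame, exemplars: Sequence[str]) -> list[str]:
    present = set(table["gene_id"])
    usable = [g for g in exemplars if g in present]
    missing = [g for g in exemplars if g not in present]
    if missing:
        logger.warning("%d exemplar gene(s) absent from the feature table: %s",
                       len(missing), missing[:5])
    if len(usable) < 2:
        raise ValueError("need at least 2 exemplar genes present in the feature table")
    return usable


def evidence_factors(
    table: pd.DataFrame, exemplars: Sequence[str]
) -> pd.DataFrame:
    """Per-feature and combined EFs for every gene in the table (unsorted).

    Clock ECDFs / fractions are trained on the exemplar rows, nonclock ones
    on all remaining rows.
    """
    usable = _usable_exemplars(table, exemplars)
    is_ex = table["gene_id"].isin(usable).to_numpy()

    out = pd.DataFrame({"gene_id": table["gene_id"].to_numpy()})
    for feat, ef_col in CONTINUOUS_FEATURES.items():
        ex_vals = table.loc[is_ex, feat].dropna()
        if len(ex_vals) < 2:
            raise ValueError(f"need >=2 non-missing exemplar values for feature {feat!r}")
        non_vals = table.loc[~is_ex, feat].dropna()
        clock = ClassConditionalECDF(ex_vals, label=f"{feat}|clock")
        nonclock = ClassConditionalECDF(non_vals, label=f"{feat}|nonclock")
        out[ef_col] = feature_evidence_factor(table[feat].to_numpy(dtype=float), clock, nonclock)
    for feat, ef_col in BOOLEAN_FEATURES.items():
        p_c, p_nc = estimate_class_fractions(table[feat], is_ex)
        out[ef_col] = boolean_bayes_factor(table[feat].to_numpy(dtype=float), p_c, p_nc)

    out["ef_combined"] = np.exp(np.sum(np.log(out[EF_COLUMNS].to_numpy(dtype=float)), axis=1))
    return out


def rank_genes(
    table: pd.DataFrame,
    exemplars: Sequence[str],
    config: RankingConfig | None = None,
) -> pd.DataFrame:
    """Ranked EvidenceResult table: EFs, posterior odds, and rank per gene.

    Descending combined evidence factor; ties break on ascending gene_id.
    Exemplar genes are scored and ranked alongside everything else.
    """
    config = config or RankingConfig()
    usable = _usable_exemplars(table, exemplars)
    prior = config.prior_odds
    if prior is None:
        n_ex = len(usable)
        prior = n_ex / (len(table) - n_ex)

    res = evidence_factors(table, exemplars)
    res["posterior_odds"] = prior * res["ef_combined"]
    res = res.sort_values(
        ["ef_combined", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    res["rank"] = np.arange(1, len(res) + 1)
    return res
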