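"""Leave-pair-out cross-validation, sensitivity curves, and screening FDR.

Every unordered pair of exemplar clock genes is withheld in turn; the chosen
ranker is retrained on the reduced exemplar set and all non-training genes
(including the withheld pair) are re-ranked.  Sensitivity at a cutoff k is
the fraction of withheld gene-instances (two per fold) ranked within the top
k.  The screening FDR at cutoff k assumes N_true genuine clock components in
the genome: expected TP = sensitivity(k) * N_true, FDR = (k - TP)/k clipped
to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import baselines, evidence


def _score_ef(table: pd.DataFrame, exemplars: Sequence[str]) -> pd.Series:
    res = evidence.evidence_factors(table, exemplars)
    return pd.Series(
        res["ef_combined"].to_numpy(), index=pd.Index(res["gene_id"], name="gene_id")
    )


def _score_gnb(table: pd.DataFrame, exemplars: Sequence[str]) -> pd.Series:
    return baselines.nb_posterior(baselines.fit_gaussian_nb(table, exemplars), table)


def _score_knb(table: pd.DataFrame, exemplars: Sequence[str]) -> pd.Series:
    return baselines.nb_posterior(baselines.fit_kernel_nb(table, exemplars), table)


#: method label -> scorer(table, exemplars) -> per-gene score (higher = more clock-like)
METHODS: dict[str, Callable[[pd.DataFrame, Sequence[str]], pd.Series]] = {
    "ef": _score_ef,
    "gnb": _score_gnb,
    "knb": _score_knb,
}


def rank_candidates(scores: pd.Series, candidates: Sequence[str]) -> pd.Series:
    """1-based ranks of ``candidates`` by descending score, ties on ascending id."""
    s = scores.loc[list(candidates)]
    order = np.lexsort((np.asarray(s.index, dtype=object), -s.to_numpy()))
    ranks = np.empty(len(s), dtype=int)
    ranks[order] = np.arange(1, len(s) + 1)
    return pd.Series(ranks, index=s.index, name="rank")


@dataclass
class SensitivityCurve:
    """Recovery of withheld exemplars as a step function of the rank cutoff."""

    method: str
    n_folds: int
    n_candidates: int
    withheld_ranks: np.ndarray  # sorted, one entry per withheld gene-instance

    @property
    def n_withheld(self) -> int:
        return int(self.withheld_ranks.size)

    def sensitivity_at(self, k: int) -> float:
        if k < 1:
            raise ValueError("rank cutoff must be >= 1")
        return float(np.searchsorted(self.withheld_ranks, k, side="right") / self.n_withheld)

    def to_table(self, cutoffs: Sequence[int] | None = None) -> pd.DataFrame:
        cutoffs = list(cutoffs) if cutoffs is not None else default_cutoffs(self.n_candidates)
        return pd.DataFrame(
            {"cutoff": cutoffs, "sensitivity": [self.sensitivity_at(k) for k in cutoffs]}
        )


def default_cutoffs(n_candidates: int) -> list[int]:
    """1..100 densely, then every 50 up to the candidate-pool size."""
    ks = list(range(1, min(100, n_candidates) + 1))
    ks += list(range(150, n_candidates + 1, 50))
    if ks[-1] != n_candidates:
        ks.append(n_candidates)
    return ks


def leave_pair_out_cv(
    table: pd.DataFrame,
    exemplars: Sequence[str],
    method: str = "ef",
) -> SensitivityCurve:
    """All C(n, 2) exemplar pairs withheld in turn; returns the recovery curve.

    Per fold the withheld pair is treated as unlabeled and competes against
    the full non-training universe; its two ranks are recorded.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid methods: {sorted(METHODS)}")
    exemplars = [g for g in exemplars if g in set(table["gene_id"])]
    if len(exemplars) < 3:
        raise ValueError("leave-pair-out CV needs at least 3 exemplars in the table")
    scorer = METHODS[method]
    all_genes = list(table["gene_id"])

    withheld_ranks: list[int] = []
    n_candidates = len(all_genes) - (len(exemplars) - 2)
    for pair in combinations(sorted(exemplars), 2):
        train = [g for g in exemplars if g not in pair]
        train_set = set(train)
        scores = scorer(table, train)
        candidates = [g for g in all_genes if g not in train_set]
        ranks = rank_candidates(scores, candidates)
        withheld_ranks.extend(int(ranks[g]) for g in pair)

    curve = SensitivityCurve(
        method=method,
        n_folds=len(exemplars) * (len(exemplars) - 1) // 2,
        n_candidates=n_candidates,
        withheld_ranks=np.sort(np.asarray(withheld_ranks)),
    )
    return curve


def sensitivity_at(curve, k: int) -> float:
    """Step-function sensitivity lookup.

    Accepts a :class:`SensitivityCurve` or a sparse ``{cutoff: sensitivity}``
    mapping (value at the greatest knot <= k; 0 below the first knot).
    """
    if k < 1:
        raise ValueError("rank cutoff must be >= 1")
    if isinstance(curve, SensitivityCurve):
        return curve.sensitivity_at(k)
    knots = sorted(curve)
    value = 0.0
    for knot in knots:
        if knot <= k:
            value = curve[knot]
        else:
            break
    return float(value)


def fdr_estimate(curve, n_true: int, k: int) -> float:
    """Screening FDR(k) = clip((k - sens(k) * N_true) / k, 0, 1)."""
    if n_true <= 0:
        raise ValueError("assumed number of true clock components must be positive")
    sens = sensitivity_at(curve, k)
    tp = sens * n_true
    return float(np.clip((k - tp) / k, 0.0, 1.0))


def fdr_table(
    curve,
    n_true_values: Sequence[int] = (25, 50, 75),
    cutoffs: Sequence[int] | None = None,
) -> pd.DataFrame:
    """FDR over a grid of assumed true-clock counts and rank cutoffs."""
    if cutoffs is None:
        if isinstance(curve, SensitivityCurve):
            cutoffs = default_cutoffs(curve.n_candidates)
        else:
            cutoffs = sorted(curve)
    rows = [
        {"n_true": n_true, "cutoff": k, "fdr": fdr_estimate(curve, n_true, k)}
        for n_true in n_true_values
        for k in cutoffs
    ]
    return pd.DataFrame(rows)


def topk_overlap(rankings: Mapping[str, Sequence[str]], k: int) -> dict:
    """Exact intersection sizes and Jaccard indices of per-method top-k lists.

    ``rankings`` maps a method label to its full gene ordering (best first);
    all orderings must cover the same gene universe.
    """
    labels = list(rankings)
    if len(labels) < 2:
        raise ValueError("need at least 2 rankings to compare")
    universes = {label: frozenset(r) for label, r in rankings.items()}
    first = next(iter(universes.values()))
    for label, uni in universes.items():
        if uni != first:
            raise ValueError(f"ranking {label!r} covers a different gene universe")

    tops = {label: set(list(r)[:k]) for label, r in rankings.items()}
    pairwise = {}
    jaccard = {}
    for a, b in combinations(labels, 2):
        inter = len(tops[a] & tops[b])
        union = len(tops[a] | tops[b])
        pairwise[(a, b)] = inter
        jaccard[(a, b)] = inter / union if union else 1.0
    out = {"k": k, "pairwise": pairwise, "jaccard": jaccard}
    if len(labels) >= 3:
        common = set.intersection(*(tops[label] for label in labels))
        out["all_methods"] = len(common)
    return out


def permutation_null_sensitivities(
    table: pd.DataFrame,
    n_exemplar: int,
    k: int,
    method: str = "ef",
    n_permutations: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Leave-pair-out sensitivity(k) under random exemplar labels.

    Reassigns the positive class to ``n_exemplar`` random genes per
    permutation; under this null a withheld gene's rank is uniform on the
    candidate pool, so E[sensitivity(k)] = k / n_candidates.
    """
    rng = np.random.default_rng(seed)
    genes = np.asarray(table["gene_id"])
    out = []
    for _ in range(n_permutations):
        fake = sorted(rng.choice(genes, size=n_exemplar, replace=False))
        curve = leave_pair_out_cv(table, fake, method=method)
        out.append(curve.sensitivity_at(k))
    return np.asarray(out)
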