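"""The five per-gene clock-feature metrics.

Each metric is constructed so that larger values are more clock-like:

* ``M_Cyc``  — -log10 of the product of per-tissue cycling p-values.
* ``M_Dist`` — |Z_period| + |Z_amp| of the most disruptive siRNA pool,
  z-scored against all screened genes.
* ``M_int``  — number of distinct exemplar clock genes adjacent in the
  genetic-interaction network (nonself).
* ubiquity   — tissue count, dichotomised at the ROC cutoff with maximal
  distance from the identity line (Youden's J).
* homology   — Boolean fly-homologue flag, passed through.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical FeatureTable column order (after gene_id)
FEATURE_COLUMNS = [
    "m_cyc",
    "m_dist",
    "m_int",
    "ubiquity_count",
    "ubiquity_flag",
    "homology_flag",
]


def cycling_metric(p_values: Iterable[float]) -> float:
    """M_Cyc = -log10 of the product of the present per-tissue p-values.

    Missing (NaN) tissues contribute a factor of 1; the metric is missing
    (NaN) only when every tissue is missing.  p-values must lie in (0, 1].
    """
    present = [p for p in p_values if not pd.isna(p)]
    if not present:
        return float("nan")
    for p in present:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    return float(-np.sum(np.log10(present)))


def cycling_metric_table(cycling: pd.DataFrame) -> pd.Series:
    """Vectorised M_Cyc over a table with ``gene_id`` plus p-value columns."""
    _check_unique_ids(cycling, "cycling")
    pcols = [c for c in cycling.columns if c != "gene_id"]
    vals = cycling[pcols].to_numpy(dtype=float)
    bad = (vals <= 0) | (vals > 1)
    if np.any(bad & ~np.isnan(vals)):
        raise ValueError("cycling p-values must lie in (0, 1]")
    with np.errstate(invalid="ignore"):
        logs = -np.log10(vals)
    m = np.nansum(logs, axis=1)
    m[np.all(np.isnan(vals), axis=1)] = np.nan
    return pd.Series(m, index=pd.Index(cycling["gene_id"], name="gene_id"), name="m_cyc")


def select_extreme_pool(screen: pd.DataFrame) -> pd.DataFrame:
    """Per gene, the single siRNA pool with the largest |Δperiod| + |Δamp|.

    Joint L1 selection over the two log-ratios, so exactly one pool
    represents each gene; ties go to the lowest pool id.
    """
    df = screen.copy()
    df["_l1"] = df["log_period_ratio"].abs() + df["log_amp_ratio"].abs()
    df = df.sort_values(["gene_id", "_l1", "pool"], ascending=[True, False, True], kind="mergesort")
    sel = df.drop_duplicates("gene_id", keep="first").drop(columns="_l1")
    return sel.reset_index(drop=True)


def disturbance_metric(screen: pd.DataFrame) -> pd.Series:
    """M_Dist = |Z_period| + |Z_amp| of each gene's selected pool.

    z-scores are taken against the across-gene distribution of selected
    values (population SD).  A degenerate zero-SD parameter contributes 0
    with a logged warning.
    """
    sel = select_extreme_pool(screen)
    if len(sel) < 2:
        raise ValueError("disturbance metric needs records for at least 2 genes")
    out = np.zeros(len(sel))
    for col in ("log_period_ratio", "log_amp_ratio"):
        x = sel[col].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0.0:
            logger.warning("degenerate screen population: %s has zero SD; Z set to 0", col)
            continue
        out += np.abs((x - x.mean()) / sd)
    return pd.Series(out, index=pd.Index(sel["gene_id"], name="gene_id"), name="m_dist")


def _dedupe_edges(edge_list: pd.DataFrame) -> set[tuple[str, str]]:
    pairs = set()
    for a, b in zip(edge_list["gene_a"], edge_list["gene_b"]):
        pairs.add((a, b) if a <= b else (b, a))
    return pairs


def interaction_metric(
    gene: str, edge_list: pd.DataFrame, exemplars: Sequence[str]
) -> int:
    """Count of distinct exemplar genes adjacent to ``gene``, excluding itself.

    Duplicate and orientation-reversed edges count once; a gene absent from
    the network has count 0.
    """
    partners = set()
    for a, b in _dedupe_edges(edge_list):
        if a == gene and b != gene:
            partners.add(b)
        elif b == gene and a != gene:
            partners.add(a)
    return len(partners & set(exemplars))


def interaction_metric_table(
    edge_list: pd.DataFrame, exemplars: Sequence[str], genes: Sequence[str]
) -> pd.Series:
    """Vectorised M_int over a gene universe (0 for edge-less genes)."""
    exemplar_set = set(exemplars)
    counts: dict[str, set] = {}
    for a, b in _dedupe_edges(edge_list):
        if a == b:  # nonself rule
            continue
        if b in exemplar_set:
            counts.setdefault(a, set()).add(b)
        if a in exemplar_set:
            counts.setdefault(b, set()).add(a)
    vals = [len(counts.get(g, ())) for g in genes]
    return pd.Series(vals, index=pd.Index(genes, name="gene_id"), name="m_int")


def ubiquity_cutoff(
    counts: pd.Series, exemplars: Sequence[str]
) -> tuple[float, pd.Series]:
    """ROC cutoff for the tissue-ubiquity count, plus per-gene flags.

    Every observed count value is swept as a candidate threshold ``t``
    (gene called "ubiquitous" when count >= t); the chosen ``t`` maximises
    Youden's J = sensitivity - FPR, i.e. the ROC point farthest from the
    identity line.  Ties break toward the smallest ``t``; ``flag = count >= t``.
    """
    counts = counts.dropna()
    exemplar_set = set(exemplars)
    is_ex = counts.index.isin(exemplar_set)
    ex_counts = counts[is_ex].to_numpy(dtype=float)
    other_counts = counts[~is_ex].to_numpy(dtype=float)
    if ex_counts.size == 0 or other_counts.size == 0:
        raise ValueError("ubiquity cutoff needs counts for both exemplar and non-exemplar genes")

    candidates = np.unique(counts.to_numpy(dtype=float))
    best_t, best_j = None, -np.inf
    for t in candidates:  # ascending, so strict > keeps the smallest tied t
        sens = np.mean(ex_counts >= t)
        fpr = np.mean(other_counts >= t)
        j = sens - fpr
        if j > best_j:
            best_j, best_t = j, t
    if best_j == 0.0:
        logger.warning("ubiquity classes are not separated (max J = 0); cutoff %g", best_t)
    flags = (counts >= best_t).astype(float)
    flags.name = "ubiquity_flag"
    return float(best_t), flags


def homology_flag(gene: str, table: Mapping[str, bool] | pd.Series) -> float:
    """Boolean fly-homology flag; absent gene -> missing (NaN)."""
    if isinstance(table, pd.Series):
        table = table.to_dict()
    if gene not in table:
        return float("nan")
    return float(bool(table[gene]))


def _check_unique_ids(df: pd.DataFrame, source: str) -> None:
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id in {source} input: {sorted(set(dup))[:5]}")


def assemble_feature_table(**columns: pd.Series) -> pd.DataFrame:
    """Outer-join named per-gene Series into one FeatureTable.

    Keys must be FeatureTable column names; entries absent from a source are
    recorded as missing.  Duplicate identifiers within one source are an
    input error naming the offender.
    """
    frames = []
    for name, series in columns.items():
        if name not in FEATURE_COLUMNS:
            raise ValueError(f"unknown feature column {name!r}; expected one of {FEATURE_COLUMNS}")
        dup = series.index[series.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene_id in source {name!r}: {sorted(set(dup))[:5]}")
        s = series.copy()
        s.name = name
        frames.append(s)
        logger.info("feature column %s: %d genes, %d missing", name, len(s), int(s.isna().sum()))
    table = pd.concat(frames, axis=1, join="outer")
    for name in FEATURE_COLUMNS:
        if name not in table.columns:
            table[name] = np.nan
    table = table[FEATURE_COLUMNS].sort_index()
    table.index.name = "gene_id"
    return table.reset_index()


def compute_feature_table(
    cycling: pd.DataFrame,
    screen: pd.DataFrame,
    edge_list: pd.DataFrame,
    ubiquity: pd.DataFrame,
    homology: pd.DataFrame,
    exemplars: Sequence[str],
    gene_universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full raw-inputs -> FeatureTable pipeline.

    ``gene_universe`` fixes the set of genes scored by the interaction count
    (edge-less genes get 0); by default it is the union of genes across all
    sources, so genes observed only outside the network still receive a count.
    """
    for df, src in ((screen, "screen"), (ubiquity, "ubiquity"), (homology, "homology")):
        if df is ubiquity or df is homology:
            _check_unique_ids(df, src)

    m_cyc = cycling_metric_table(cycling)
    m_dist = disturbance_metric(screen)
    ub_counts = pd.Series(
        ubiquity["n_tissues"].to_numpy(dtype=float),
        index=pd.Index(ubiquity["gene_id"], name="gene_id"),
        name="ubiquity_count",
    )
    hom = pd.Series(
        homology["has_fly_homolog"].to_numpy(dtype=float),
        index=pd.Index(homology["gene_id"], name="gene_id"),
        name="homology_flag",
    )

    if gene_universe is None:
        universe = set(m_cyc.index) | set(m_dist.index) | set(ub_counts.index) | set(hom.index)
        universe |= set(edge_list["gene_a"]) | set(edge_list["gene_b"])
        gene_universe = sorted(universe)
    m_int = interaction_metric_table(edge_list, exemplars, list(gene_universe))

    cutoff, flags = ubiquity_cutoff(ub_counts, exemplars)
    logger.info("ubiquity ROC cutoff: count >= %g", cutoff)

    return assemble_feature_table(
        m_cyc=m_cyc,
        m_dist=m_dist,
        m_int=m_int,
        ubiquity_count=ub_counts,
        ubiquity_flag=flags,
        homology_flag=hom,
    )
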