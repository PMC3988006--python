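"""Independent brute-force oracles used to check the library implementations.

Everything here counts events directly with explicit loops/arithmetic and
stays deliberately independent of the code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def brute_ef(m, clock_vals, nonclock_vals):
    """Tail-ratio evidence factor by direct counting, with the same
    exemplar-max capping and denominator flooring as the engine."""
    if np.isnan(m):
        return 1.0
    clock_vals = list(clock_vals)
    nonclock_vals = list(nonclock_vals)
    m_cap = min(m, max(clock_vals))
    s_c = sum(1 for v in clock_vals if v >= m_cap) / len(clock_vals)
    s_nc = sum(1 for v in nonclock_vals if v >= m_cap) / len(nonclock_vals)
    if s_nc == 0.0:
        s_nc = 1.0 / (len(nonclock_vals) + 1)
    return s_c / s_nc


def brute_boolean_ef(flag, clock_flags, nonclock_flags):
    """Boolean Bayes factor from Laplace-smoothed class frequencies."""
    if np.isnan(flag):
        return 1.0
    c = [f for f in clock_flags if not np.isnan(f)]
    nc = [f for f in nonclock_flags if not np.isnan(f)]
    p_c = (sum(1 for f in c if f != 0) + 1.0) / (len(c) + 2.0)
    p_nc = (sum(1 for f in nc if f != 0) + 1.0) / (len(nc) + 2.0)
    if flag != 0:
        return p_c / p_nc
    return (1.0 - p_c) / (1.0 - p_nc)


def brute_ubiquity_cutoff(ex_counts, other_counts):
    """Exhaustive Youden-J search over all observed counts (smallest tied t)."""
    candidates = sorted(set(list(ex_counts) + list(other_counts)))
    best_t, best_j = None, -np.inf
    for t in candidates:
        sens = sum(1 for c in ex_counts if c >= t) / len(ex_counts)
        fpr = sum(1 for c in other_counts if c >= t) / len(other_counts)
        if sens - fpr > best_j:
            best_j, best_t = sens - fpr, t
    return best_t


def adjacency_interaction_counts(edges, genes, exemplars):
    """M_int via an explicit adjacency matrix (nonself, deduplicated)."""
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        if a in idx and b in idx and a != b:
            adj[idx[a], idx[b]] = True
            adj[idx[b], idx[a]] = True
    ex_idx = [idx[g] for g in exemplars if g in idx]
    return {g: int(adj[idx[g], ex_idx].sum()) for g in genes}


def conditionally_independent_population(rng, n_features=3, max_levels=3):
    """Discrete population with exact conditional independence given class.

    Each class's genes are the full Cartesian product of per-feature value
    lists, so empirical joint tail probabilities factor exactly.  Both
    classes share each feature's top value, which keeps every tail count
    positive and the exemplar-max cap inactive.
    """
    tables = {}
    for label in ("clock", "nonclock"):
        lists = []
        for _ in range(n_features):
            k = rng.integers(2, max_levels + 1)
            vals = list(rng.integers(1, 4, size=k - 1)) + [4]  # shared top value
            lists.append([float(v) for v in vals])
        tables[label] = [list(combo) for combo in itertools.product(*lists)]
    return tables["clock"], tables["nonclock"]


def enumerated_posterior_odds(clock_rows, nonclock_rows, m_vector):
    """P(clock | joint tail event) / P(nonclock | ...) by explicit enumeration."""
    def joint_tail(rows):
        return sum(1 for row in rows if all(v >= m for v, m in zip(row, m_vector)))

    a_c = joint_tail(clock_rows)
    a_nc = joint_tail(nonclock_rows)
    # posterior odds = P(D|C)P(C) / (P(D|NC)P(NC)) with P(class) = size/total
    return (a_c / len(clock_rows)) * len(clock_rows) / (
        (a_nc / len(nonclock_rows)) * len(nonclock_rows)
    )


def random_feature_table(rng, n_genes, missing_rate=0.1):
    """Random FeatureTable-shaped frame with NaN missingness."""
    ids = [f"g{i:04d}" for i in range(n_genes)]
    df = pd.DataFrame(
        {
            "gene_id": ids,
            "m_cyc": rng.gamma(2.0, 2.0, n_genes),
            "m_dist": rng.exponential(1.5, n_genes),
            "m_int": rng.integers(0, 8, n_genes).astype(float),
            "ubiquity_count": rng.poisson(5.0, n_genes).astype(float),
            "ubiquity_flag": (rng.random(n_genes) < 0.4).astype(float),
            "homology_flag": (rng.random(n_genes) < 0.3).astype(float),
        }
    )
    for col in df.columns[1:]:
        mask = rng.random(n_genes) < missing_rate
        df.loc[mask, col] = np.nan
    return df
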