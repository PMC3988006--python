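import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import adjacency_interaction_counts, brute_ubiquity_cutoff
from clockrank.metrics import (
    assemble_feature_table,
    cycling_metric,
    cycling_metric_table,
    disturbance_metric,
    homology_flag,
    interaction_metric,
    interaction_metric_table,
    select_extreme_pool,
    ubiquity_cutoff,
)


class TestCyclingMetric:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((1.0, 1.0, 1.0), 0.0),
            ((0.001, 0.01, 0.1), 6.0),
            ((0.01, np.nan, np.nan), 2.0),  # missing tissues contribute factor 1
        ],
    )
    def test_hand_checked_values(self, triple, expected):
        assert cycling_metric(triple) == pytest.approx(expected, abs=1e-12)

    def test_all_missing_yields_missing_not_zero(self):
        assert np.isnan(cycling_metric([np.nan, np.nan, np.nan]))

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_out_of_range_pvalues_rejected(self, bad):
        with pytest.raises(ValueError):
            cycling_metric([bad, 0.5, 0.5])

    @given(
        ps=st.lists(
            st.floats(min_value=1e-10, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=3,
        )
    )
    def test_tissue_order_invariance_and_additivity(self, ps):
        forward = cycling_metric(ps)
        assert forward == pytest.approx(cycling_metric(ps[::-1]))
        assert forward == pytest.approx(sum(-np.log10(p) for p in ps), rel=1e-9)


class TestDisturbanceMetric:
    def test_pool_with_largest_l1_norm_selected(self):
        screen = pd.DataFrame(
            {
                "gene_id": ["a", "a"],
                "pool": [1, 2],
                "log_period_ratio": [0.1, -0.9],
                "log_amp_ratio": [0.5, 0.0],
            }
        )
        sel = select_extreme_pool(screen)
        assert list(sel["pool"]) == [2]  # |−0.9|+0 = 0.9 > 0.6

    def test_gene_at_population_mean_scores_zero(self):
        # symmetric population: gene 'b' sits exactly at both means
        screen = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "pool": [1, 1, 1],
                "log_period_ratio": [-1.0, 0.0, 1.0],
                "log_amp_ratio": [2.0, 3.0, 4.0],
            }
        )
        m = disturbance_metric(screen)
        assert m["b"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_zscore_arithmetic(self, rng):
        genes = [f"g{i}" for i in range(40)]
        screen = pd.DataFrame(
            {
                "gene_id": genes * 2,
                "pool": [1] * 40 + [2] * 40,
                "log_period_ratio": rng.normal(size=80),
                "log_amp_ratio": rng.normal(size=80),
            }
        )
        m = disturbance_metric(screen)
        sel = select_extreme_pool(screen).set_index("gene_id")
        zp =(sel["log_period_ratio"] - sel["log_period_ratio"].mean()) / sel[
            "log_period_ratio"
        ].std(ddof=0)
        za = (sel["log_amp_ratio"] - sel["log_amp_ratio"].mean()) / sel[
            "log_amp_ratio"
        ].std(ddof=0)
        expected = zp.abs() + za.abs()
        assert np.allclose(m.loc[expected.index], expected)

    def test_location_and_scale_invariance(self, rng):
        genes = [f"g{i}" for i in range(30)]
        screen = pd.DataFrame(
            {
                "gene_id": genes,
                "pool": [1] * 30,
                "log_period_ratio": rng.normal(size=30),
                "log_amp_ratio": rng.normal(size=30),
            }
        )
        base = disturbance_metric(screen)
        shifted = screen.copy()
        shifted["log_period_ratio"] = shifted["log_period_ratio"] * 3.0 + 7.0
        shifted["log_amp_ratio"] = shifted["log_amp_ratio"] * 0.5 - 2.0
        # z-scores are affine-invariant per parameter, but selection uses raw
        # magnitudes, so only single-pool tables transform cleanly
        assert np.allclose(disturbance_metric(shifted), base)

    def test_degenerate_population_warns_and_zeroes(self, caplog):
        screen = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "pool": [1, 1],
                "log_period_ratio": [1.0, 1.0],
                "log_amp_ratio": [0.0, 2.0],
            }
        )
        with caplog.at_level("WARNING"):
            m = disturbance_metric(screen)
        assert "zero SD" in caplog.text
        assert m["a"] == pytest.approx(1.0)  # only amplitude contributes

    def test_single_gene_rejected(self):
        screen = pd.DataFrame(
            {"gene_id": ["a"], "pool": [1], "log_period_ratio": [1.0], "log_amp_ratio": [1.0]}
        )
        with pytest.raises(ValueError):
            disturbance_metric(screen)


class TestInteractionMetric:
    def test_empty_edge_list(self):
        edges = pd.DataFrame({"gene_a": [], "gene_b": []})
        assert interaction_metric("a", edges, ["b"]) == 0

    def test_counts_distinct_exemplar_neighbours(self):
        edges = pd.DataFrame(
            {"gene_a": ["a", "a", "a"], "gene_b": ["b", "c", "d"]}
        )
        assert interaction_metric("a", edges, ["b", "c"]) == 2

    def test_self_loops_excluded(self):
        edges = pd.DataFrame({"gene_a": ["b", "b"], "gene_b": ["b", "c"]})
        assert interaction_metric("b", edges, ["b", "c"]) == 1

    def test_duplicate_and_reversed_edges_count_once(self):
        edges = pd.DataFrame(
            {"gene_a": ["a", "b", "a"], "gene_b": ["b", "a", "b"]}
        )
        assert interaction_metric("a", edges, ["b"]) == 1

    def test_matches_adjacency_matrix_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 50))
            genes = [f"g{i}" for i in range(n)]
            n_edges = int(rng.integers(0, 3 * n))
            pairs = [
                (genes[rng.integers(n)], genes[rng.integers(n)]) for _ in range(n_edges)
            ]
            edges = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
            exemplars = list(rng.choice(genes, size=min(5, n), replace=False))
            expected = adjacency_interaction_counts(pairs, genes, exemplars)
            got = interaction_metric_table(edges, exemplars, genes)
            assert {g: int(v) for g, v in got.items()} == expected


class TestUbiquityCutoff:
    def test_perfect_separation_picks_smallest_separating_count(self):
        counts = pd.Series(
            [20, 25, 1, 2], index=["e1", "e2", "x1", "x2"], name="ubiquity_count"
        )
        t, flags = ubiquity_cutoff(counts, ["e1", "e2"])
        assert t == 20  # smallest observed count with J = 1
        assert flags[["e1", "e2"]].tolist() == [1.0, 1.0]
        assert flags[["x1", "x2"]].tolist() == [0.0, 0.0]

    def test_identical_distributions_warn_with_zero_j(self, caplog):
        counts = pd.Series([5, 5, 5, 5], index=["e1", "e2", "x1", "x2"])
        with caplog.at_level("WARNING"):
            t, flags = ubiquity_cutoff(counts, ["e1", "e2"])
        assert t == 5
        assert "not separated" in caplog.text

    def test_brute_force_example(self):
        counts = pd.Series(
            [3, 5, 5, 1, 2, 3, 4],
            index=["e1", "e2", "e3", "x1", "x2", "x3", "x4"],
        )
        t, _ = ubiquity_cutoff(counts, ["e1", "e2", "e3"])
        assert t == 5  # J = 2/3 beats J = 1/2 at t = 3

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n_ex = int(rng.integers(2, 10))
            n_other = int(rng.integers(2, 90))
            ex = rng.poisson(10, n_ex)
            other = rng.poisson(4, n_other)
            idx = [f"e{i}" for i in range(n_ex)] + [f"x{i}" for i in range(n_other)]
            counts = pd.Series(np.concatenate([ex, other]).astype(float), index=idx)
            t, _ = ubiquity_cutoff(counts, [f"e{i}" for i in range(n_ex)])
            assert t == brute_ubiquity_cutoff(ex, other)

    def test_requires_both_classes(self):
        counts = pd.Series([1.0, 2.0], index=["e1", "e2"])
        with pytest.raises(ValueError):
            ubiquity_cutoff(counts, ["e1", "e2"])


class TestHomologyFlag:
    def test_passthrough_and_missing(self):
        table = pd.Series({"a": True, "b": False})
        assert homology_flag("a", table) == 1.0
        assert homology_flag("b", table) == 0.0
        assert np.isnan(homology_flag("zzz", table))


class TestAssemble:
    def test_gene_in_single_source_has_other_features_missing(self):
        table = assemble_feature_table(
            m_cyc=pd.Series({"a": 1.0}), m_dist=pd.Series({"b": 2.0})
        )
        row = table.set_index("gene_id").loc["a"]
        assert row["m_cyc"] == 1.0
        assert row[["m_dist", "m_int", "ubiquity_count", "ubiquity_flag", "homology_flag"]].isna().all()

    def test_disjoint_sources_union_size(self):
        table = assemble_feature_table(
            m_cyc=pd.Series(dict.fromkeys("abc", 1.0)),
            m_dist=pd.Series(dict.fromkeys("def", 2.0)),
        )
        assert len(table) == 6

    def test_duplicate_identifiers_rejected_by_name(self):
        dup = pd.Series([1.0, 2.0], index=["a", "a"])
        with pytest.raises(ValueError, match="m_cyc"):
            assemble_feature_table(m_cyc=dup)

    def test_unknown_column_rejected(self):
        with pytest.raises(ValueError, match="unknown feature column"):
            assemble_feature_table(bogus=pd.Series({"a": 1.0}))

    def test_full_synthetic_pipeline_row_count(self, default_table):
        assert len(default_table) == 1000
        assert list(default_table.columns) == [
            "gene_id",
            "m_cyc",
            "m_dist",
            "m_int",
            "ubiquity_count",
            "ubiquity_flag",
            "homology_flag",
        ]


def test_cycling_metric_table_matches_scalar_version(rng):
    df = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c"],
            "p_liver": [0.01, np.nan, 1.0],
            "p_pituitary": [0.1, 0.5, np.nan],
            "p_nih3t3": [np.nan, np.nan, np.nan],
        }
    )
    got = cycling_metric_table(df)
    for g in df["gene_id"]:
        row = df.set_index("gene_id").loc[g]
        expected = cycling_metric(row.tolist())
        if np.isnan(expected):
            assert np.isnan(got[g])
        else:
            assert got[g] == pytest.approx(expected)
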