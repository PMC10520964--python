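import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tardistress import simulate
from tardistress.expression import (
    HitRecord,
    bh_adjust,
    call_degs,
    classify_temperature_pattern,
    cpm_transform,
    detect_outlier_samples,
    estimate_unwanted_factors,
    group_genes_by_best_hit,
    hypergeometric_enrichment,
    select_empirical_controls,
)


class TestCpm:
    def test_single_sample_arithmetic(self):
        counts = pd.DataFrame({"s1": [1, 3]}, index=["g1", "g2"])
        cpm = cpm_transform(counts)
        np.testing.assert_allclose(cpm["s1"], [250000.0, 750000.0])

    def test_columns_sum_to_a_million(self, small_experiment):
        counts, _, _ = small_experiment
        cpm = cpm_transform(counts)
        np.testing.assert_allclose(cpm.sum(axis=0), 1e6)

    def test_row_normalized_constant_rows_are_zero(self):
        counts = pd.DataFrame(
            {"s1": [5, 1], "s2": [5, 1]}, index=["g1", "g2"]
        )
        out = cpm_transform(counts, log=True, row_normalize=True)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            cpm_transform(counts)


def brute_force_grouping(hits, contigs):
    """Oracle: group contigs by best hit using explicit enumeration."""
    gene = {}
    for c in contigs:
        mine = [h for h in hits if h.query_id == c]
        if not mine:
            gene[c] = c
            continue
        best = min(mine, key=lambda h: (-h.bitscore, h.e_value, h.subject_id))
        gene[c] = best.subject_id
    return gene


def hit(q, s, bits, evalue=1e-30):
    return HitRecord(q, s, 90.0, 100, 1, 0, 1, 100, 1, 100, evalue, bits)


class TestGeneGrouping:
    def test_shared_best_hit_merges_contigs(self):
        hits = [hit("A", "P1", 100), hit("B", "P1", 90), hit("C", "P2", 80)]
        g = group_genes_by_best_hit(hits, ["A", "B", "C"])
        assert g == {"A": "P1", "B": "P1", "C": "P2"}

    def test_no_hit_contig_is_singleton(self):
        g = group_genes_by_best_hit([hit("A", "P1", 50)], ["A", "B"])
        assert g["B"] == "B"

    def test_bitscore_tie_broken_by_evalue_then_subject(self):
        hits = [hit("A", "P2", 100, 1e-20), hit("A", "P1", 100, 1e-30)]
        g = group_genes_by_best_hit(hits, ["A"])
        assert g["A"] == "P1"
        hits = [hit("A", "P2", 100, 1e-30), hit("A", "P1", 100, 1e-30)]
        assert group_genes_by_best_hit(hits, ["A"])["A"] == "P1"

    def test_matches_brute_force_and_order_invariant(self):
        rng = np.random.default_rng(4)
        contigs = [f"c{i}" for i in range(12)]
        proteins = [f"P{i}" for i in range(4)]
        hits = []
        for c in contigs:
            for p in rng.choice(proteins, size=int(rng.integers(0, 4)), replace=False):
                hits.append(hit(c, str(p), float(rng.integers(50, 200)),
                                10.0 ** -int(rng.integers(5, 50))))
        expected = brute_force_grouping(hits, contigs)
        assert group_genes_by_best_hit(hits, contigs) == expected
        rng.shuffle(hits)
        assert group_genes_by_best_hit(hits, contigs) == expected

    def test_synthetic_hit_table_recovers_true_partition(self):
        true_map = {f"c{i}": f"P{i % 3}" for i in range(9)}
        true_map["lonely"] = None
        records = simulate.generate_hit_table(true_map, n_decoys=2, seed=0)
        contigs = list(true_map)
        g = group_genes_by_best_hit(records, contigs)
        for c, p in true_map.items():
            assert g[c] == (p if p is not None else c)


class TestBhAdjust:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.05, 0.01]), [0.05, 0.02])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_adjusted_dominates_input_and_matches_step_up_oracle(self):
        def step_up(p):
            """Independent reference: sort, scale by m/rank, enforce
            monotonicity from the largest p down."""
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p)
            scaled = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(scaled[::-1])[::-1]
            out = np.empty(m)
            out[order] = np.minimum(adj, 1.0)
            return out

        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, 50)
        q = bh_adjust(p)
        assert (q >= p).all() and (q <= 1).all()
        np.testing.assert_allclose(q, step_up(p))

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]])
    def test_invalid_pvalues_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


def exact_hypergeom_upper_tail(N, K, n, k):
    """Oracle: enumerate P(overlap >= k) from binomial coefficients."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
    ) / total


class TestEnrichment:
    def annotation(self, genes_with_term):
        return pd.DataFrame(
            {"gene_id": list(genes_with_term), "term_id": "T1"}
        )

    def test_worked_example_p_equals_one_over_42(self):
        universe = [f"g{i}" for i in range(10)]
        ann = self.annotation(universe[:5])
        res = hypergeometric_enrichment(universe[:4], universe, ann)
        row = res.iloc[0]
        assert row["p_value"] == pytest.approx(1 / 42)
        assert row["o_over_e"] == pytest.approx(2.0)
        assert not row["significant"]  # O/E must exceed 3

    def test_matches_exhaustive_enumeration_small_universes(self):
        for N in (5, 8, 12):
            universe = [f"g{i}" for i in range(N)]
            for K, n in itertools.product(range(1, N + 1), range(1, N + 1)):
                deg = universe[:n]
                ann = self.annotation(universe[:K])
                k = len(set(universe[:K]) & set(deg))
                res = hypergeometric_enrichment(deg, universe, ann)
                assert res.iloc[0]["p_value"] == pytest.approx(
                    exact_hypergeom_upper_tail(N, K, n, k)
                )

    def test_zero_overlap(self):
        universe = [f"g{i}" for i in range(10)]
        ann = self.annotation(universe[5:8])  # disjoint from DEG set
        res = hypergeometric_enrichment(universe[:2], universe, ann)
        assert res.iloc[0]["observed"] == 0
        assert res.iloc[0]["o_over_e"] == 0.0
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_term_without_universe_genes_skipped(self):
        universe = [f"g{i}" for i in range(6)]
        ann = pd.DataFrame({"gene_id": ["other1", "other2"], "term_id": "T9"})
        res = hypergeometric_enrichment(universe[:2], universe, ann)
        assert res.empty

    def test_planted_annotation_significance_rule(self):
        universe = [f"g{i}" for i in range(200)]
        deg = universe[:20]
        ann = simulate.generate_annotation(universe, deg, 12, 10,
                                           n_background_terms=5, seed=1)
        res = hypergeometric_enrichment(deg, universe, ann).set_index("term_id")
        row = res.loc["TERM:0001"]
        assert row["o_over_e"] == pytest.approx(10 / (20 * 12 / 200))
        assert row["significant"]  # strong planted overlap

    def test_infeasible_planted_overlap_rejected(self):
        universe = [f"g{i}" for i in range(10)]
        with pytest.raises(ValueError):
            simulate.generate_annotation(universe, universe[:4], 0, 0)
        with pytest.raises(ValueError):
            simulate.generate_annotation(universe, universe[:4], 3, 4)


class TestControlsAndFactors:
    def test_controls_are_mostly_truly_null(self, small_experiment):
        counts, design, truth = small_experiment
        controls = select_empirical_controls(counts, design, n_controls=100)
        frac_null = (~truth["genes"].loc[controls, "is_de"]).mean()
        assert frac_null >= 0.8

    def test_requesting_all_genes_returns_all(self, small_experiment):
        counts, design, _ = small_experiment
        with pytest.warns(UserWarning):
            controls = select_empirical_controls(counts, design, n_controls=10**6)
        assert len(controls) <= counts.shape[0]

    def test_factor_contract_and_k_zero(self, small_experiment):
        counts, _, _ = small_experiment
        genes = list(counts.index[:50])
        uf = estimate_unwanted_factors(counts, genes, 2)
        assert uf.W.shape == (counts.shape[1], 2)
        np.testing.assert_allclose(np.linalg.norm(uf.W, axis=0), 1.0)
        uf0 = estimate_unwanted_factors(counts, genes, 0)
        assert uf0.W.shape == (counts.shape[1], 0)
        with pytest.raises(ValueError):
            estimate_unwanted_factors(counts, genes, counts.shape[1])

    def test_planted_batch_factor_recovered(self):
        cfg = simulate.ExpressionGenConfig(
            n_genes=600, frac_de=0.1, per_step_log2fc=0.5,
            batch_log2fc=1.0, batch_gene_fraction=0.6, seed=5,
        )
        counts, design, truth = simulate.generate_expression_experiment(cfg)
        controls = select_empirical_controls(counts, design, n_controls=200)
        uf = estimate_unwanted_factors(counts, controls, 1)
        batch = (truth["samples"]["batch"] == "B").to_numpy(dtype=float)
        r = np.corrcoef(uf.W[:, 0], batch)[0, 1]
        assert abs(r) > 0.9


class TestOutliers:
    def test_identical_samples_not_flagged(self):
        counts = pd.DataFrame(
            np.tile([[5], [9], [2]], (1, 4)),
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(4)],
        )
        design = pd.DataFrame(
            {"temperature_C": [5, 5, 10, 10], "exposure": ["ST"] * 4,
             "replicate": [1, 2, 1, 2]},
            index=counts.columns,
        )
        assert detect_outlier_samples(counts, design) == []

    def test_planted_shifted_sample_flagged(self):
        cfg = simulate.ExpressionGenConfig(
            n_genes=2000, frac_de=0.0, n_outliers=1, seed=0
        )
        counts, design, truth = simulate.generate_expression_experiment(cfg)
        planted = truth["samples"].index[truth["samples"]["is_outlier"]][0]
        assert planted in detect_outlier_samples(counts, design)

    def test_homogeneous_groups_rarely_flagged(self):
        flagged_runs = 0
        for seed in range(20):
            cfg = simulate.ExpressionGenConfig(n_genes=2000, frac_de=0.0, seed=seed)
            counts, design, _ = simulate.generate_expression_experiment(cfg)
            flagged_runs += bool(detect_outlier_samples(counts, design))
        assert flagged_runs <= 1


class TestDegCalling:
    def test_constant_gene_is_never_significant(self):
        rng = np.random.default_rng(0)
        counts, design, _ = simulate.generate_expression_experiment(
            simulate.ExpressionGenConfig(n_genes=50, frac_de=0.0, seed=1,
                                         exposures=("ST",))
        )
        counts.iloc[0] = 500  # identical in every sample
        lib_equal = counts.sum(axis=0)
        counts = (counts * (lib_equal.max() / lib_equal)).round().astype(int)
        counts.iloc[0] = 500
        res = call_degs(counts, design, exposure="ST")
        gene = counts.index[0]
        if gene in res.index:  # survives the expression filter
            assert res.loc[gene, "p_value"] > 0.5
            assert not res.loc[gene, "significant"]

    def test_planted_monotone_degs_recovered_with_direction(self, small_experiment):
        counts, design, truth = small_experiment
        res = call_degs(counts, design, exposure="ST")
        de = truth["genes"]["is_de"]
        planted = de[de].index.intersection(res.index)
        recovered = res.loc[planted, "significant"]
        assert recovered.mean() >= 0.9
        rec_idx = recovered[recovered].index
        agree = (
            res.loc[rec_idx, "direction"]
            == truth["genes"].loc[rec_idx, "direction"]
        ).mean()
        assert agree >= 0.95

    def test_exposure_subset_and_exclude_15C(self, small_experiment):
        counts, design, _ = small_experiment
        res = call_degs(counts, design, exposure="LT", exclude_15C=True)
        assert res["log2_fc_15C"].isna().all()
        assert res["log2_fc_20C"].notna().all()

    def test_adjusted_calling_beats_unadjusted_under_batch(self):
        cfg = simulate.ExpressionGenConfig(
            n_genes=600, frac_de=0.1, per_step_log2fc=0.5,
            batch_log2fc=1.0, batch_gene_fraction=0.6, seed=5,
        )
        counts, design, truth = simulate.generate_expression_experiment(cfg)
        controls = select_empirical_controls(counts, design, n_controls=200)
        uf = estimate_unwanted_factors(counts, controls, 1)
        de = truth["genes"]["is_de"]
        plain = call_degs(counts, design, exposure="ST")
        adj = call_degs(counts, design, W=uf, exposure="ST")
        n_plain = plain.loc[de[de].index.intersection(plain.index), "significant"].sum()
        n_adj = adj.loc[de[de].index.intersection(adj.index), "significant"].sum()
        assert n_adj > n_plain


class TestPatternClassification:
    @pytest.mark.parametrize(
        "means,expected",
        [([1, 2, 3, 4], "up"), ([4, 3, 2, 1], "down"), ([2, 2, 2, 2], "flat")],
    )
    def test_slope_sign_labels(self, means, expected):
        s = pd.Series(means, index=[5, 10, 15, 20])
        assert classify_temperature_pattern(s) == expected
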