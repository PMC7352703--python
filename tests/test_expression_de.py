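import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endotx import data_path
from endotx.expression_de import (CountMatrix, QcSummary, bh_adjust,
                                  consensus_de, delta_delta_ct,
                                  filter_expressed, hypergeometric_enrichment,
                                  nb_de_test, pca_samples, poisson_distance,
                                  qc_totals, size_factors_median_of_ratios)


def cm_from(counts, groups=None):
    counts = np.asarray(counts)
    return CountMatrix(
        feature_ids=[f"g{i}" for i in range(counts.shape[0])],
        sample_ids=[f"s{j}" for j in range(counts.shape[1])],
        counts=counts,
        group_labels=groups or [],
    )


class TestFilterExpressed:
    def test_half_of_samples_retained(self):
        cm = cm_from([[1, 2, 3, 0, 0, 0]])
        assert filter_expressed(cm, 0.5).n_features == 1

    def test_all_zero_dropped(self):
        cm = cm_from([[0, 0, 0, 0], [1, 1, 1, 1]])
        assert filter_expressed(cm).feature_ids == ["g1"]

    def test_full_fraction_equals_brute_force(self, rng):
        counts = rng.integers(0, 4, size=(300, 6))
        cm = cm_from(counts)
        kept = filter_expressed(cm, 1.0).feature_ids
        want = [f"g{i}" for i in range(300) if (counts[i] > 0).all()]
        assert kept == want

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_expressed(cm_from(np.zeros((0, 4), dtype=int)))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = cm_from([[10, 10], [7, 7]])
        np.testing.assert_allclose(size_factors_median_of_ratios(cm), [1, 1])

    def test_doubled_sample_has_double_factor(self):
        cm = cm_from([[10, 20], [100, 200], [5, 10]])
        f = size_factors_median_of_ratios(cm)
        np.testing.assert_allclose(f[1] / f[0], 2.0)
        # hand computation: every ratio to the geometric mean is sqrt(1/2)
        np.testing.assert_allclose(f, [math.sqrt(0.5), math.sqrt(2)], rtol=1e-12)

    def test_no_common_feature_is_an_error(self):
        cm = cm_from([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors_median_of_ratios(cm)


class TestPoissonDistance:
    def test_duplicate_samples_at_distance_zero(self):
        cm = cm_from([[10, 10, 50], [5, 5, 2], [9, 9, 14]])
        d = poisson_distance(cm)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] > 0

    def test_symmetry_and_zero_diagonal(self, rng):
        cm = cm_from(rng.integers(1, 100, size=(50, 5)))
        d = poisson_distance(cm)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0)

    def test_groups_separate(self, rng):
        """Two groups with 4-fold shifts on 20% of genes: within-group mean
        distance is smaller than between-group."""
        n_genes = 200
        mu = np.exp(rng.normal(np.log(100), 0.5, n_genes))
        shift = np.ones(n_genes)
        shift[rng.choice(n_genes, n_genes // 5, replace=False)] = 4.0
        size = 1 / 0.05
        a = rng.negative_binomial(size, size / (size + mu[:, None]), (n_genes, 3))
        mu2 = mu * shift
        b = rng.negative_binomial(size, size / (size + mu2[:, None]), (n_genes, 3))
        cm = cm_from(np.hstack([a, b]), ["A"] * 3 + ["B"] * 3)
        d = poisson_distance(cm)
        within = np.mean([d[i, j] for i in range(3) for j in range(3) if i != j]
                         + [d[i, j] for i in range(3, 6) for j in range(3, 6)
                            if i != j])
        between = np.mean([d[i, j] for i in range(3) for j in range(3, 6)])
        assert within < between


class TestPca:
    def test_identical_samples_score_zero(self):
        cm = cm_from(np.tile([[10], [30], [7]], (1, 4)))
        scores, _ = pca_samples(cm)
        np.testing.assert_allclose(scores[:, 0], 0, atol=1e-8)

    def test_variance_fractions_valid(self, rng):
        cm = cm_from(rng.integers(1, 200, size=(100, 6)))
        _, var = pca_samples(cm, n_components=3)
        assert np.all(var >= 0) and np.all(np.diff(var) <= 1e-12)
        assert var.sum() <= 1 + 1e-9

    def test_groups_separate_on_pc1(self, rng):
        n_genes, size = 300, 1 / 0.05
        mu = np.exp(rng.normal(np.log(100), 0.5, n_genes))
        shift = np.ones(n_genes)
        shift[rng.choice(n_genes, n_genes // 5, replace=False)] = 4.0
        a = rng.negative_binomial(size, size / (size + mu[:, None]), (n_genes, 3))
        mu2 = mu * shift
        b = rng.negative_binomial(size, size / (size + mu2[:, None]), (n_genes, 3))
        cm = cm_from(np.hstack([a, b]), ["A"] * 3 + ["B"] * 3)
        scores, _ = pca_samples(cm)
        from sklearn.metrics import silhouette_score
        assert silhouette_score(scores[:, :1], [0, 0, 0, 1, 1, 1]) > 0


class TestNbDeTest:
    def test_null_type_one_error_calibrated(self):
        """Empirical type-I error at alpha 0.05 sits inside the binomial 99%
        CI over 2000 null NB features (10 replicates per group)."""
        rng = np.random.default_rng(7)
        n, n_feat, size = 10, 2000, 1 / 0.05
        mu = np.exp(rng.normal(np.log(100), 1, n_feat))
        counts = rng.negative_binomial(size, size / (size + mu[:, None]),
                                       (n_feat, 2 * n))
        cm = cm_from(counts, ["A"] * n + ["B"] * n)
        p = np.array([r.p_value for r in nb_de_test(cm)])
        rate = (p < 0.05).mean()
        half_width = 2.576 * math.sqrt(0.05 * 0.95 / n_feat)
        assert abs(rate - 0.05) < half_width

    def test_all_zero_feature_degenerates(self):
        counts = np.array([[0, 0, 0, 0, 0, 0], [10, 12, 9, 11, 10, 13]])
        cm = cm_from(counts, ["A"] * 3 + ["B"] * 3)
        res = nb_de_test(cm)
        assert res[0].log2_fc == 0 and res[0].p_value == 1

    def test_spiked_fold_change_recovered(self):
        """log2FC 2 spikes (mean 100, dispersion 0.05, 3v3) are estimated
        with the right sign and within 1 unit for >= 90% of 500 spikes."""
        rng = np.random.default_rng(42)
        n_null, n_spike, size = 2000, 500, 1 / 0.05
        mu = np.exp(rng.normal(np.log(100), 1, n_null))
        null = rng.negative_binomial(size, size / (size + mu[:, None]),
                                     (n_null, 6))
        c1 = rng.negative_binomial(size, size / (size + 100), (n_spike, 3))
        c2 = rng.negative_binomial(size, size / (size + 400), (n_spike, 3))
        counts = np.vstack([null, np.hstack([c1, c2])])
        cm = cm_from(counts, ["A"] * 3 + ["B"] * 3)
        fc = np.array([r.log2_fc for r in nb_de_test(cm)])[n_null:]
        assert (fc > 0).mean() >= 0.90
        assert (np.abs(fc - 2) < 1).mean() >= 0.90


class TestBhAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_values_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, float("nan")])

    def test_order_invariance_and_statsmodels_agreement(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500)
        adj = bh_adjust(p)
        perm = rng.permutation(500)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])
        np.testing.assert_allclose(adj, multipletests(p, method="fdr_bh")[1])

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=200)
        assert (bh_adjust(p) >= p - 1e-12).all()


def de_table(ids, padj, fc):
    return pd.DataFrame({"feature_id": ids, "p_adjusted": padj, "log2_fc": fc})


class TestConsensusDe:
    def test_empty_table_gives_empty_consensus(self):
        t1 = de_table(["a", "b"], [0.01, 0.01], [1, 1])
        t2 = de_table([], [], [])
        frame, venn = consensus_de([t1, t2])
        assert len(frame) == 0 and venn["consensus"] == 0

    def test_identical_tables_reproduce_single_set(self):
        t = de_table(["a", "b", "c"], [0.01, 0.2, 0.001], [1, 1, -2])
        frame, venn = consensus_de([t, t.copy(), t.copy()])
        assert set(frame["feature_id"]) == {"a", "c"}
        assert venn["consensus"] == 2

    def test_discordant_sign_excluded(self):
        t1 = de_table(["a"], [0.01], [1.0])
        t2 = de_table(["a"], [0.01], [-1.0])
        frame, _ = consensus_de([t1, t2])
        assert len(frame) == 0

    def test_duplicate_feature_rejected(self):
        t = de_table(["a", "a"], [0.01, 0.01], [1, 1])
        with pytest.raises(ValueError):
            consensus_de([t, t])

    def test_matches_brute_force_set_logic(self, rng):
        ids = [f"f{i}" for i in range(200)]
        tables = []
        for _ in range(3):
            tables.append(de_table(ids, rng.uniform(size=200),
                                   rng.normal(size=200)))
        frame, _ = consensus_de(tables, alpha=0.3)
        want = set(ids)
        for t in tables:
            want &= set(t.loc[t["p_adjusted"] < 0.3, "feature_id"])
        want = {f for f in want
                if len({np.sign(float(t.set_index("feature_id")
                                       .loc[f, "log2_fc"])) for t in tables}) == 1}
        assert set(frame["feature_id"]) == want


class TestHypergeometricEnrichment:
    def test_matches_enumeration_on_toy_universe(self):
        universe = [f"u{i}" for i in range(20)]
        query = set(universe[:7])
        gene_set = set(universe[3:12])
        res = hypergeometric_enrichment(query, {"S": gene_set}, universe)
        k = len(query & gene_set)
        p_enum = sum(
            math.comb(len(gene_set), x) * math.comb(20 - len(gene_set), 7 - x)
            / math.comb(20, 7)
            for x in range(k, min(7, len(gene_set)) + 1)
        )
        assert res["p"].iloc[0] == pytest.approx(p_enum, rel=1e-12)

    def test_query_equal_to_set_minimises_p(self):
        universe = [f"u{i}" for i in range(30)]
        gene_set = set(universe[:5])
        res = hypergeometric_enrichment(gene_set, {"S": gene_set}, universe)
        p_min = 1 / math.comb(30, 5)
        assert res["p"].iloc[0] == pytest.approx(p_min, rel=1e-9)

    def test_disjoint_query_is_not_enriched(self):
        universe = [f"u{i}" for i in range(30)]
        res = hypergeometric_enrichment(set(universe[:5]),
                                        {"S": set(universe[10:15])}, universe)
        assert res["overlap"].iloc[0] == 0
        assert res["p"].iloc[0] == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), {"S": set()}, set())


class TestQcTotals:
    def test_library_summary_pair_totals(self):
        """The six-library sequencing summary sums to the published pair
        totals (raw 282,664,081; uniquely mapped 216,501,753)."""
        qc = QcSummary.from_tsv(data_path("library_qc.tsv"))
        totals = qc_totals(qc)
        assert totals["raw_reads"] == 282_664_081
        assert totals["trimmed_reads"] == 260_974_918
        assert totals["uniquely_mapped"] == 216_501_753

    def test_all_zero_summary(self):
        qc = QcSummary(["s1"], [0], [0], [0], [0], [0], [0])
        assert qc_totals(qc)["raw_reads"] == 0

    def test_odd_total_rejected(self):
        qc = QcSummary(["s1"], [3], [2], [2], [2], [0], [0])
        with pytest.raises(ValueError, match="odd"):
            qc_totals(qc)

    def test_hierarchy_enforced(self):
        with pytest.raises(ValueError):
            QcSummary(["s1"], [10], [12], [8], [8], [0], [0])


class TestDeltaDeltaCt:
    def test_one_cycle_shift_doubles_expression(self):
        target = {"c1": 20.0, "c2": 20.0, "t1": 19.0, "t2": 19.0}
        refs = {s: [15.0, 15.0] for s in target}
        groups = {"c1": "CTR", "c2": "CTR", "t1": "LPS", "t2": "LPS"}
        fold, _ = delta_delta_ct(target, refs, groups, "CTR")
        assert fold["CTR"] == pytest.approx(1.0)
        assert fold["LPS"] == pytest.approx(2.0)

    def test_t_statistic_matches_hand_formula(self):
        # 3v3 toy table with distinct dCT values
        target = {"c1": 21.0, "c2": 20.5, "c3": 20.0,
                  "t1": 19.0, "t2": 18.5, "t3": 19.5}
        refs = {s: [15.0, 16.0] for s in target}
        groups = {s: ("CTR" if s.startswith("c") else "LPS") for s in target}
        _, p = delta_delta_ct(target, refs, groups, "CTR")
        dct_c = [21.0 - 15.5, 20.5 - 15.5, 20.0 - 15.5]
        dct_t = [19.0 - 15.5, 18.5 - 15.5, 19.5 - 15.5]
        sp2 = (np.var(dct_c, ddof=1) * 2 + np.var(dct_t, ddof=1) * 2) / 4
        t_hand = (np.mean(dct_t) - np.mean(dct_c)) / math.sqrt(sp2 * (2 / 3))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=4)
        assert p == pytest.approx(p_hand, rel=1e-12)

    def test_missing_ct_rejected(self):
        target = {"c1": 20.0, "t1": float("nan")}
        refs = {s: [15.0, 15.0] for s in target}
        with pytest.raises(ValueError, match="missing"):
            delta_delta_ct(target, refs, {"c1": "CTR", "t1": "LPS"}, "CTR")
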