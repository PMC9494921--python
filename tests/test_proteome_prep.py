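"""LFQ matrix preparation: normalisation, run correction, missingness
filter, imputation, differential expression, clustering and PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuroscreen.exceptions import ContractError, InvalidInputError
from neuroscreen.proteome_prep import (LfqMatrix, cluster_category_test,
                                       diff_expr, filter_missing,
                                       hcluster_individuals,
                                       impute_protein_means,
                                       min_required_quantified,
                                       pca_individuals, remove_run_effect,
                                       spearman_distance_matrix,
                                       vsn_log2_normalize)
from neuroscreen.synthetic_data import SimConfig, gen_lfq_matrix


def raw_matrix(values, runs=None, categories=None):
    n_p, n_i = values.shape
    individuals = [f"I{j + 1}" for j in range(n_i)]
    frame = pd.DataFrame(values, index=[f"P{i + 1}" for i in range(n_p)],
                         columns=individuals)
    runs = pd.Series(runs if runs is not None else ["run1"] * n_i,
                     index=individuals)
    cats = (pd.Series(categories, index=individuals)
            if categories is not None else None)
    return LfqMatrix(values=frame, runs=runs, categories=cats, stage="raw")


class TestStageOrder:
    def test_out_of_order_calls_rejected(self):
        m = raw_matrix(np.full((12, 4), 100.0))
        with pytest.raises(ContractError):
            remove_run_effect(m)  # needs normalized
        with pytest.raises(ContractError):
            impute_protein_means(m)  # needs filtered
        norm = vsn_log2_normalize(m)
        with pytest.raises(ContractError):
            vsn_log2_normalize(norm)  # cannot renormalise


class TestVsnNormalize:
    def test_multiplicative_offset_removed(self, rng):
        base = rng.lognormal(10, 1, size=(50, 1))
        values = np.hstack([base, 2.0 * base])
        out = vsn_log2_normalize(raw_matrix(values))
        v = out.values.to_numpy()
        np.testing.assert_allclose(v[:, 0], v[:, 1], atol=1e-6)

    def test_variance_stabilisation_on_lognormal(self):
        # SD-vs-mean dependence must weaken after the transform
        m, _ = gen_lfq_matrix(SimConfig(seed=10, n_proteins=500,
                                        missing_rate_slope=0.0))
        raw = m.values.to_numpy()
        out = vsn_log2_normalize(m).values.to_numpy()
        rho_before = stats.spearmanr(raw.mean(axis=1),
                                     raw.std(axis=1)).statistic
        rho_after = stats.spearmanr(out.mean(axis=1),
                                    out.std(axis=1)).statistic
        assert abs(rho_after) < abs(rho_before)

    def test_constant_matrix_stays_constant(self):
        out = vsn_log2_normalize(raw_matrix(np.full((15, 3), 7.0)))
        assert np.unique(out.values.to_numpy()).size == 1

    def test_rank_order_preserved_within_sample(self, rng):
        values = rng.lognormal(8, 2, size=(40, 3))
        out = vsn_log2_normalize(raw_matrix(values))
        for j in range(3):
            assert np.array_equal(np.argsort(values[:, j]),
                                  np.argsort(out.values.to_numpy()[:, j]))

    def test_sparse_sample_rejected(self):
        values = np.full((12, 2), 50.0)
        values[3:, 1] = np.nan
        with pytest.raises(InvalidInputError, match="I2"):
            vsn_log2_normalize(raw_matrix(values))


class TestRemoveRunEffect:
    def norm(self, values, runs):
        m = raw_matrix(2.0 ** np.asarray(values, dtype=float), runs)
        return vsn_log2_normalize(m)

    def test_single_run_identity(self, small_lfq):
        m = small_lfq(np.arange(12.0).reshape(3, 4))
        out = remove_run_effect(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_constant_offset_removed_and_grand_mean_kept(self, small_lfq, rng):
        log2 = rng.normal(20, 1, size=(30, 10))
        log2[:, 5:] += 1.0  # +1 log2 on run 2
        runs = ["run1"] * 5 + ["run2"] * 5
        m = small_lfq(log2, runs=runs)
        out = remove_run_effect(m)
        v = out.values.to_numpy()
        per_run_diff = v[:, 5:].mean(axis=1) - v[:, :5].mean(axis=1)
        assert np.abs(per_run_diff).max() < 1e-10
        np.testing.assert_allclose(v.mean(axis=1), log2.mean(axis=1),
                                   atol=1e-10)

    def test_protein_absent_from_one_run(self, small_lfq):
        log2 = np.full((2, 6), 10.0)
        log2[0, 3:] = np.nan  # protein P1 unobserved in run 2
        log2[0, :3] = [9.0, 10.0, 11.0]
        m = small_lfq(log2, runs=["run1"] * 3 + ["run2"] * 3)
        out = remove_run_effect(m)
        # run-1 values unchanged up to re-centring on the grand mean
        v = out.values.to_numpy()[0, :3]
        np.testing.assert_allclose(v - v.mean(), [-1.0, 0.0, 1.0],
                                   atol=1e-12)
        assert out.values.iloc[0, 3:].isna().all()


class TestFilterAndImpute:
    def test_boundary_at_five_missing_of_43(self, small_lfq):
        log2 = np.full((3, 43), 10.0)
        log2[0, :5] = np.nan  # missing in exactly 5 -> removed
        log2[1, :4] = np.nan  # missing in 4 -> kept
        m = small_lfq(log2)
        out = filter_missing(m, max_missing=4)
        assert list(out.values.index) == ["P2", "P3"]

    def test_min_required_quantified_rule(self):
        assert min_required_quantified(43, 4) == 39

    def test_no_missing_identity(self, small_lfq, rng):
        m = small_lfq(rng.normal(size=(6, 5)))
        out = filter_missing(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_all_filtered_warns_and_keeps_columns(self, small_lfq):
        log2 = np.full((2, 10), np.nan)
        log2[:, 0] = 1.0
        m = small_lfq(log2)
        with pytest.warns(UserWarning):
            out = filter_missing(m, max_missing=4)
        assert out.n_proteins == 0
        assert list(out.values.columns) == list(m.values.columns)

    def test_impute_uses_protein_mean(self, small_lfq):
        log2 = np.array([[1.0, 2.0, 3.0, np.nan]])
        m = filter_missing(small_lfq(log2), max_missing=1)
        out, fraction = impute_protein_means(m)
        assert out.values.iloc[0, 3] == pytest.approx(2.0)
        assert fraction == pytest.approx(1 / 4)

    def test_study_scale_accounting(self, small_lfq, rng):
        # 1841 proteins x 43 individuals = 79,163 observations; with 646
        # entries missing the imputed fraction is ~0.8%
        log2 = rng.normal(size=(1841, 43))
        flat = rng.choice(1841 * 43, size=646, replace=False)
        log2.ravel()[flat] = np.nan
        m = small_lfq(log2)
        assert m.total_observations() == 79_163
        filt = filter_missing(m, max_missing=43)  # keep everything
        out, fraction = impute_protein_means(filt)
        assert fraction == pytest.approx(646 / 79_163)
        assert round(100 * fraction, 1) == 0.8
        assert out.n_missing() == 0

    def test_filter_never_alters_retained_values(self, small_lfq, rng):
        log2 = rng.normal(size=(20, 8))
        log2[0, :6] = np.nan
        m = small_lfq(log2)
        out = filter_missing(m)
        kept = out.values.index
        pd.testing.assert_frame_equal(out.values, m.values.loc[kept])


class TestDiffExpr:
    def test_planted_shift_recovered(self, small_lfq, rng):
        n_a, n_b = 14, 15
        log2 = rng.normal(20, 0.5, size=(1000, n_a + n_b))
        log2[:50, n_a:] += 2.0  # 50 planted proteins shifted +2 log2
        cats = ["LP-NCI"] * n_a + ["AD"] * n_b
        m = small_lfq(log2, categories=cats)
        res = diff_expr(m, ("AD", "LP-NCI"))
        sig = {r.protein for r in res if r.significant}
        planted = {f"P{i + 1}" for i in range(50)}
        sensitivity = len(sig & planted) / 50
        fdp = len(sig - planted) / max(len(sig), 1)
        assert sensitivity >= 0.9
        assert fdp <= 0.1

    def test_null_false_positive_control(self, small_lfq):
        false_rates = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            log2 = rng.normal(size=(300, 20))
            cats = ["A"] * 10 + ["B"] * 10
            m = small_lfq(log2, categories=cats)
            res = diff_expr(m, ("A", "B"))
            false_rates.append(np.mean([r.significant for r in res]))
        assert np.mean(false_rates) <= 0.05

    def test_single_protein_q_scales_by_two_stage_factor(self, small_lfq, rng):
        # the two-stage step-up runs its first stage at alpha/(1+alpha),
        # so with m = 1 the adjusted q is p*(1+alpha), not p itself
        log2 = rng.normal(size=(1, 12))
        m = small_lfq(log2, categories=["A"] * 6 + ["B"] * 6)
        res = diff_expr(m, ("A", "B"))
        assert res[0].q == pytest.approx(min(1.0, res[0].p * 1.05))

    def test_welch_statistic_matches_scipy(self, small_lfq, rng):
        log2 = rng.normal(size=(5, 16))
        m = small_lfq(log2, categories=["A"] * 7 + ["B"] * 9)
        res = diff_expr(m, ("A", "B"))
        for i, r in enumerate(res):
            t, p = stats.ttest_ind(log2[i, :7], log2[i, 7:], equal_var=False)
            assert r.t_stat == pytest.approx(t)
            assert r.p == pytest.approx(p)

    def test_insufficient_observations_excluded(self, small_lfq):
        log2 = np.full((2, 8), 10.0)
        log2[0, :2] = np.nan  # only 2 observed in category A
        m = small_lfq(log2, categories=["A"] * 4 + ["B"] * 4)
        res = diff_expr(m, ("A", "B"))
        assert [r.protein for r in res] == ["P2"]


def complete_linkage_oracle(dist):
    """Naive O(n^3) agglomerative complete linkage; returns merge heights."""
    clusters = [{i} for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return np.array(heights)


class TestClustering:
    def imputed(self, small_lfq, log2):
        m = small_lfq(log2)
        return impute_protein_means(filter_missing(m))[0]

    def test_duplicate_individuals_merge_at_zero(self, small_lfq, rng):
        log2 = rng.normal(size=(30, 4))
        log2[:, 1] = log2[:, 0]
        m = self.imputed(small_lfq, log2)
        _, link = hcluster_individuals(m, k=2)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_planted_blocks_recovered(self, small_lfq, rng):
        base1 = rng.normal(size=30)
        base2 = rng.normal(size=30)
        cols = ([base1 + rng.normal(0, 0.25, 30) for _ in range(3)]
                + [base2 + rng.normal(0, 0.25, 30) for _ in range(3)])
        m = self.imputed(small_lfq, np.column_stack(cols))
        labels, _ = hcluster_individuals(m, k=2)
        assert labels.iloc[:3].nunique() == 1
        assert labels.iloc[3:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[3]

    def test_merge_heights_match_naive_oracle(self, small_lfq):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            log2 = rng.normal(size=(25, 5))
            m = self.imputed(small_lfq, log2)
            dist = spearman_distance_matrix(m).to_numpy()
            _, link = hcluster_individuals(m, k=2)
            oracle = complete_linkage_oracle(dist)
            np.testing.assert_allclose(np.sort(link[:, 2]),
                                       np.sort(oracle), atol=1e-12)

    def test_monotone_transform_invariance(self, small_lfq, rng):
        log2 = np.abs(rng.normal(size=(40, 6))) + 1.0
        m1 = self.imputed(small_lfq, log2)
        m2 = self.imputed(small_lfq, log2 ** 3)  # strictly monotone map
        _, l1 = hcluster_individuals(m1, k=3)
        _, l2 = hcluster_individuals(m2, k=3)
        np.testing.assert_allclose(l1, l2, atol=1e-12)

    def test_constant_individual_rejected_by_name(self, small_lfq):
        log2 = np.random.default_rng(1).normal(size=(10, 3))
        log2[:, 2] = 5.0
        m = self.imputed(small_lfq, log2)
        with pytest.raises(ContractError, match="I3"):
            hcluster_individuals(m, k=2)


class TestClusterCategoryTest:
    def test_hand_computed_2x2(self):
        labels = pd.Series([1] * 10 + [2] * 10,
                           index=[f"I{i}" for i in range(20)])
        cats = pd.Series(["x"] * 10 + ["y"] * 10, index=labels.index)
        chi2, p, table = cluster_category_test(labels, cats)
        assert chi2 == pytest.approx(20.0)
        assert table.to_numpy().tolist() == [[10, 0], [0, 10]]

    def test_identical_distribution_gives_zero(self):
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        cats = pd.Series(["x", "y", "x", "y"], index=list("abcd"))
        chi2, p, _ = cluster_category_test(labels, cats)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_null_p_uniformity(self):
        # independent labels: the p-value distribution is ~U(0,1)
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(500):
            labels = pd.Series(rng.integers(1, 3, 60),
                               index=[f"I{i}" for i in range(60)])
            cats = pd.Series(rng.choice(["x", "y", "z"], 60),
                             index=labels.index)
            try:
                ps.append(cluster_category_test(labels, cats)[1])
            except InvalidInputError:
                continue
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPca:
    def test_rank_one_matrix_single_component(self, small_lfq, rng):
        u = rng.normal(size=(30, 1))
        v = rng.normal(size=(1, 6))
        m = impute_protein_means(filter_missing(small_lfq(u @ v)))[0]
        _, evr = pca_individuals(m)
        assert evr[0] >= 0.999

    def test_duplicated_individual_identical_scores(self, small_lfq, rng):
        log2 = rng.normal(size=(30, 5))
        log2[:, 4] = log2[:, 0]
        m = impute_protein_means(filter_missing(small_lfq(log2)))[0]
        scores, _ = pca_individuals(m)
        np.testing.assert_allclose(scores.iloc[0], scores.iloc[4], atol=1e-9)

    def test_two_block_structure_separates_on_pcs(self, small_lfq):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            log2 = rng.normal(size=(80, 12))
            log2[:40, 6:] += 1.5  # block structure
            m = impute_protein_means(filter_missing(small_lfq(log2)))[0]
            scores, _ = pca_individuals(m)
            from sklearn.metrics import silhouette_score
            s = silhouette_score(scores[["PC1", "PC2"]], [0] * 6 + [1] * 6)
            hits += s > 0
        assert hits >= 18
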