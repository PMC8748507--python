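"""Overlap tests, normalization, similarity models, NB differential test."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import binom

from origin_atlas import origin


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestOverlapFraction:
    def test_identical_sets(self):
        a = bed([("chr1", 0, 100), ("chr1", 200, 300)])
        assert origin.overlap_fraction(a, a.copy()) == 1.0

    def test_disjoint_sets(self):
        a = bed([("chr1", 0, 100)])
        b = bed([("chr1", 500, 600)])
        assert origin.overlap_fraction(a, b) == 0.0

    def test_three_of_four(self):
        a = bed([("chr1", 0, 100), ("chr1", 200, 300), ("chr1", 400, 500), ("chr2", 0, 100)])
        b = bed([("chr1", 50, 450)])
        assert origin.overlap_fraction(a, b) == 0.75

    def test_empty_cancer_set_rejected(self):
        with pytest.raises(ValueError):
            origin.overlap_fraction(bed([]), bed([("chr1", 0, 10)]))


class TestPermutationOverlap:
    def test_exact_binomial_tail(self):
        # frozen oracle: P(X >= 6 | n=10, p=0.5) = 386/1024
        assert binom.sf(5, 10, 0.5) == pytest.approx(386 / 1024, rel=1e-12)

    def test_p_value_wiring_matches_binomial(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.choice(np.arange(0, 100_000, 100), 300, replace=False)) * 10
        pooled = bed([("chr1", s, s + 500) for s in starts])
        celltype = pooled.iloc[rng.choice(300, 80, replace=False)]
        cancer = pooled.iloc[rng.choice(300, 50, replace=False)]
        out = origin.permutation_overlap_test(
            {"c": cancer}, {"t": celltype}, pooled, n_perm=50, seed=1)
        row = out.iloc[0]
        n = len(cancer)
        k = int(round(row.observed_fraction * n))
        assert row.p_value == pytest.approx(binom.sf(k - 1, n, row.expected_fraction), rel=1e-12)
        assert row.p_adjusted >= row.p_value

    def test_celltype_equals_pool_is_null(self):
        rng = np.random.default_rng(2)
        starts = np.sort(rng.choice(np.arange(0, 50_000), 200, replace=False)) * 1000
        pooled = bed([("chr1", s, s + 500) for s in starts])
        cancer = pooled.iloc[rng.choice(200, 100, replace=False)]
        out = origin.permutation_overlap_test(
            {"c": cancer}, {"t": pooled}, pooled, n_perm=20, seed=3)
        row = out.iloc[0]
        assert row.expected_fraction == pytest.approx(row.observed_fraction, abs=1e-9)
        assert row.p_value > 0.3

    def test_n_perm_validated(self):
        a = bed([("chr1", 0, 10)])
        with pytest.raises(ValueError):
            origin.permutation_overlap_test({"c": a}, {"t": a}, a, n_perm=0)


class TestNormalization:
    def test_logcpm_worked_example(self):
        counts = pd.DataFrame({"s1": [0, 10 ** 6], "s2": [0, 10 ** 6]})
        out = origin.logcpm_normalize(counts, prior=5)
        # c=0, L=1e6: log2(5e6 / 1,000,010) = log2(4.99995)
        assert out.iloc[0, 0] == pytest.approx(np.log2(5e6 / 1_000_010), rel=1e-12)
        assert out.iloc[0, 0] == pytest.approx(2.3219, abs=1e-3)

    def test_equal_inputs_equal_outputs_and_monotone(self):
        counts = pd.DataFrame({"s1": [5, 10, 20], "s2": [5, 10, 20]})
        out = origin.logcpm_normalize(counts)
        pd.testing.assert_series_equal(out["s1"], out["s2"], check_names=False)
        assert out["s1"].is_monotonic_increasing

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            origin.logcpm_normalize(pd.DataFrame({"s1": [0, 0]}))

    def test_quantile_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(origin.quantile_normalize(m), m)

    def test_quantile_two_by_two(self):
        m = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = origin.quantile_normalize(m)
        assert sorted(out["a"]) == [1.5, 3.5]
        assert sorted(out["b"]) == [1.5, 3.5]

    @given(
        st.lists(st.floats(-50, 50), min_size=6, max_size=6, unique=True),
        st.permutations(range(6)), st.permutations(range(6)), st.permutations(range(6)),
    )
    @settings(max_examples=50, deadline=None)
    def test_quantile_sorted_columns_identical(self, base, p1, p2, p3):
        # tie-free columns: after normalization every sorted column equals
        # the cross-column mean quantile profile exactly
        base = np.array(base)
        x = np.column_stack([base, base[list(p1)], base[list(p2)], base[list(p3)]])
        out = origin.quantile_normalize(pd.DataFrame(x))
        s = np.sort(out.values, axis=0)
        np.testing.assert_allclose(s - s[:, [0]], 0.0, atol=1e-9)

    def test_quantile_ties_get_mean_of_quantile_values(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [10.0, 20.0, 30.0]})
        out = origin.quantile_normalize(m)
        ref = np.sort(m.values, axis=0).mean(axis=1)
        assert out["a"].iloc[0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out["a"].iloc[1] == out["a"].iloc[0]


class TestCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        ref = pd.DataFrame(rng.random((50, 3)), columns=["t0", "t1", "t2"])
        tumor = ref[["t1"]].rename(columns={"t1": "sample1"})
        corr, _ = origin.correlate_samples_celltypes(tumor, ref)
        assert corr.loc["sample1", "t1"] == pytest.approx(1.0)
        assert corr.loc["sample1"].idxmax() == "t1"

    def test_group_averaging(self):
        rng = np.random.default_rng(1)
        ref = pd.DataFrame(rng.random((50, 4)), columns=["a1", "a2", "b1", "b2"])
        tumor = pd.DataFrame(rng.random((50, 3)), columns=["s1", "s2", "s3"], index=ref.index)
        grouped, _ = origin.correlate_samples_celltypes(
            tumor, ref, groups={"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        raw, _ = origin.correlate_samples_celltypes(tumor, ref)
        np.testing.assert_allclose(
            grouped["A"].values, raw[["a1", "a2"]].mean(axis=1).values, rtol=1e-12)

    def test_too_few_shared_peaks(self):
        a = pd.DataFrame({"s": [1.0, 2.0]}, index=["p1", "p2"])
        with pytest.raises(ValueError):
            origin.correlate_samples_celltypes(a, a.rename(columns={"s": "t"}))


class TestPseudobulkPanel:
    @staticmethod
    def _adata(n_cells=120, n_peaks=40, n_types=11, seed=0):
        rng = np.random.default_rng(seed)
        X = sp.csr_matrix(rng.poisson(2, (n_cells * n_types, n_peaks)).astype(float))
        labels = np.repeat([f"t{i:02d}" for i in range(n_types)], n_cells)
        return ad.AnnData(
            X=X,
            obs=pd.DataFrame({"cell_type": labels},
                             index=[f"c{i}" for i in range(X.shape[0])]),
            var=pd.DataFrame(index=[f"p{i}" for i in range(n_peaks)]),
        )

    def test_eleven_groups_give_220_columns(self):
        a = self._adata(n_cells=60)
        panel, labels, raw = origin.build_pseudobulk_panel(a, a.obs["cell_type"], seed=0)
        assert panel.shape[1] == 220
        assert labels.value_counts().eq(20).all()

    def test_replicate_sums_conserved_and_reproducible(self):
        a = self._adata(n_cells=60, n_types=3)
        _, _, raw1 = origin.build_pseudobulk_panel(a, a.obs["cell_type"], seed=5)
        _, _, raw2 = origin.build_pseudobulk_panel(a, a.obs["cell_type"], seed=5)
        pd.testing.assert_frame_equal(raw1, raw2)
        depth = np.asarray(a.X.sum(axis=1)).ravel()
        # every replicate column sum is a sum of 50 member cell depths
        assert raw1.sum(axis=0).max() <= np.sort(depth)[-50:].sum()

    def test_small_type_warns_and_samples_with_replacement(self):
        a = self._adata(n_cells=10, n_types=2)
        with pytest.warns(UserWarning, match="replacement"):
            panel, _, _ = origin.build_pseudobulk_panel(a, a.obs["cell_type"], seed=0)
        assert panel.shape[1] == 40


class TestSimilarityModels:
    @staticmethod
    def _panel(n_types=3, reps=12, n_feat=60, seed=0, sep=4.0):
        rng = np.random.default_rng(seed)
        cols, labels = {}, {}
        for t in range(n_types):
            centroid = np.abs(rng.normal(4, 1, n_feat))
            centroid[t * (n_feat // n_types):(t + 1) * (n_feat // n_types)] += sep
            for r in range(reps):
                name = f"t{t}_r{r}"
                cols[name] = np.abs(centroid + rng.normal(0, 0.4, n_feat))
                labels[name] = f"t{t}"
        panel = pd.DataFrame(cols, index=[f"p{i}" for i in range(n_feat)])
        return panel, pd.Series(labels)

    def test_offset_formula(self):
        panel, labels = self._panel(n_types=10, reps=4)
        models = origin.train_similarity_models(
            panel, labels, panel.index, n_folds=4, n_lambda=5, seed=0)
        m = models[0]
        assert m.class_fraction == pytest.approx(0.1)
        assert m.offset == pytest.approx(np.log(1 / 9), abs=1e-9)
        assert m.offset == pytest.approx(-2.19722, abs=1e-5)

    def test_separable_panel_scores_own_replicates_highest(self):
        panel, labels = self._panel(seed=1)
        models = origin.train_similarity_models(panel, labels, panel.index, n_folds=4, seed=0)
        scores = origin.predict_similarity(models, panel)
        assert (scores["argmax"].values == labels.values).all()

    def test_infinite_penalty_gives_half_everywhere(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 10))
        y = (rng.random(30) < 0.5).astype(float)
        betas = origin._logistic_lasso_path(X, y, np.zeros(30), np.array([1e6]))
        assert (betas == 0).all()
        from scipy.special import expit
        assert expit(X @ betas[0]).max() == 0.5

    def test_lasso_matches_statsmodels_at_fixed_lambda(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n, p = 80, 12
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:3] = [1.5, -1.0, 0.8]
        offset = np.full(n, -0.5)
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta + offset)))).astype(float)
        lam = 0.05
        mine = origin._logistic_lasso_path(X, y, offset, np.array([lam]), tol=1e-9)[0]
        glm = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset)
        ref = glm.fit_regularized(method="elastic_net", alpha=lam, L1_wt=1.0).params
        np.testing.assert_allclose(mine, ref, atol=2e-3)

    def test_scores_invariant_to_duplicating_every_class(self):
        panel, labels = self._panel(seed=2)
        X = panel.T.values
        Xs = (X - X.mean(0)) / np.where(X.std(0) == 0, 1, X.std(0))
        y = (labels.values == "t0").astype(float)
        f = y.mean()
        off = np.full(len(y), np.log(f / (1 - f)))
        lams = np.geomspace(0.2, 0.002, 8)
        b1 = origin._logistic_lasso_path(Xs, y, off, lams)
        b2 = origin._logistic_lasso_path(
            np.vstack([Xs, Xs]), np.concatenate([y, y]), np.concatenate([off, off]), lams)
        np.testing.assert_allclose(b1, b2, atol=1e-8)

    def test_feature_mismatch_rejected(self):
        panel, labels = self._panel()
        models = origin.train_similarity_models(panel, labels, panel.index, n_folds=4,
                                                n_lambda=4, seed=0)
        with pytest.raises(ValueError):
            models[0].predict(panel.iloc[:10])


class TestDifferentialPeaks:
    def test_identical_groups_nothing_passes(self):
        counts = pd.DataFrame(
            np.tile([[10], [40], [100]], (1, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        out = origin.differential_peaks(counts, groups, 0.5, 0.5, -10)
        assert (out["logFC"] == 0).all()
        assert not out["significant"].any()

    def test_group_size_validated(self):
        counts = pd.DataFrame({"s1": [1], "s2": [2], "s3": [3]})
        groups = pd.Series(["A", "B", "B"], index=counts.columns)
        with pytest.raises(ValueError):
            origin.differential_peaks(counts, groups)

    def test_poisson_limit_matches_conditional_binomial(self):
        # dispersion 0: the conditional law is Binomial(total, n1/(n1+n2))
        y1, y2, n1, n2 = 30, 12, 3, 3
        p = origin._exact_nb_pvalue(y1, y2, n1, n2, 0.0)
        total = y1 + y2
        pmf = binom.pmf(np.arange(total + 1), total, 0.5)
        expected = pmf[pmf <= pmf[y1] + 1e-15].sum()
        assert p == pytest.approx(expected, rel=1e-9)

    def test_prefilter_removes_low_mean_high_sd(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(50, (20, 6)).astype(float)
        base[0] = [0, 0, 1, 0, 0, 0]      # mean < 1
        base[1] = [1, 100, 1, 100, 1, 100]  # sd > 10
        counts = pd.DataFrame(base, columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        out = origin.differential_peaks(counts, groups, prefilter=True)
        assert 0 not in out.index and 1 not in out.index

    def test_exact_p_monotone_under_stronger_imbalance(self):
        ps = [origin._exact_nb_pvalue(20 + d, 20 - d, 3, 3, 0.05) for d in (0, 5, 10, 15)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
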