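"""NB GLM engine: fits, dispersion, tests, adjustment, classification."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from osmoloop.io import CountTable
from osmoloop.nbdiff import (
    ClassRule,
    anchor_gene_trajectories,
    bh_adjust,
    classify,
    design_matrix,
    estimate_dispersion,
    filter_features,
    fit_nb_glm,
    lrt_test,
    wald_test,
    zscore_kmeans,
)
from osmoloop.simulate import make_gene_truth, simulate_rna_counts


def two_group_design(n_per_group: int) -> pd.DataFrame:
    samples = [f"s{i}" for i in range(2 * n_per_group)]
    return pd.DataFrame(
        {"condition": ["a"] * n_per_group + ["b"] * n_per_group}, index=samples
    )


class TestDesignMatrix:
    def test_treatment_coding(self):
        d = two_group_design(2)
        X = design_matrix(d, ["condition"])
        assert list(X.columns) == ["intercept", "condition[b]"]
        np.testing.assert_array_equal(X["condition[b]"], [0, 0, 1, 1])

    def test_rank_deficiency_names_aliased_columns(self):
        d = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "u", "v", "v"]},
            index=list("pqrs"),
        )
        with pytest.raises(ValueError, match="aliased"):
            design_matrix(d, ["a", "b"])

    def test_unknown_factor(self):
        with pytest.raises(ValueError, match="not in design"):
            design_matrix(two_group_design(2), ["nope"])


class TestFit:
    def test_intercept_only_returns_log_mean(self, rng):
        counts = pd.DataFrame(
            rng.poisson(50, (20, 8)), columns=[f"s{i}" for i in range(8)]
        )
        X = pd.DataFrame({"intercept": np.ones(8)}, index=counts.columns)
        fit = fit_nb_glm(counts, X, dispersions=np.full(20, 1e-8))
        np.testing.assert_allclose(
            fit.coef["intercept"], np.log(counts.mean(axis=1)), rtol=1e-6
        )

    def test_two_group_lfc_recovery(self, rng):
        # group means 10 and 40 -> log2FC = 2
        n = 50
        counts = pd.DataFrame(
            np.hstack([rng.poisson(10, (200, n)), rng.poisson(40, (200, n))]),
            columns=[f"s{i}" for i in range(2 * n)],
        )
        X = design_matrix(two_group_design(n), ["condition"])
        fit = fit_nb_glm(counts, X)
        lfc = fit.coef["condition[b]"] / np.log(2)
        assert abs(lfc.mean() - 2.0) < 0.1

    def test_all_zero_feature_flagged_and_untested(self):
        counts = pd.DataFrame(
            [[0, 0, 0, 0], [5, 6, 7, 8]], columns=[f"s{i}" for i in range(4)]
        )
        X = design_matrix(two_group_design(2), ["condition"])
        fit = fit_nb_glm(counts, X)
        assert fit.all_zero.iloc[0] and not fit.all_zero.iloc[1]
        res = wald_test(fit, "condition[b]")
        assert np.isnan(res.pvalue.iloc[0])

    def test_matches_statsmodels_at_fixed_dispersion(self, rng):
        """Independent cross-check: same NB GLM solved by statsmodels."""
        alpha = 0.2
        counts = pd.DataFrame(
            rng.negative_binomial(5, 5 / (5 + 30.0), size=(5, 12)),
            columns=[f"s{i}" for i in range(12)],
        )
        X = design_matrix(two_group_design(6), ["condition"])
        fit = fit_nb_glm(counts, X, dispersions=np.full(5, alpha))
        for k in range(5):
            ref = sm.GLM(
                counts.iloc[k].to_numpy(),
                X.to_numpy(),
                family=sm.families.NegativeBinomial(alpha=alpha),
            ).fit()
            np.testing.assert_allclose(fit.coef.iloc[k], ref.params, rtol=1e-4, atol=1e-5)
            np.testing.assert_allclose(fit.se.iloc[k], ref.bse, rtol=1e-3, atol=1e-4)

    def test_no_residual_df_rejected(self):
        counts = pd.DataFrame([[1, 2]], columns=["s0", "s1"])
        X = pd.DataFrame(
            {"intercept": [1, 1], "c": [0, 1]}, index=["s0", "s1"]
        )
        with pytest.raises(ValueError, match="residual"):
            fit_nb_glm(counts, X)


class TestDispersion:
    def test_poisson_data_near_floor(self, rng):
        counts = pd.DataFrame(
            rng.poisson(100, (300, 8)), columns=[f"s{i}" for i in range(8)]
        )
        X = design_matrix(two_group_design(4), ["condition"])
        disp = estimate_dispersion(counts, X)
        assert disp.median() < 0.01

    def test_nb_dispersion_recovered(self, rng):
        alpha = 0.5
        size = 1 / alpha
        counts = pd.DataFrame(
            rng.negative_binomial(size, size / (size + 100.0), size=(400, 8)),
            columns=[f"s{i}" for i in range(8)],
        )
        X = design_matrix(two_group_design(4), ["condition"])
        disp = estimate_dispersion(counts, X)
        assert 0.3 < disp.median() < 0.8

    def test_constant_counts_floor(self):
        counts = pd.DataFrame(
            np.full((3, 8), 20), columns=[f"s{i}" for i in range(8)]
        )
        X = design_matrix(two_group_design(4), ["condition"])
        disp = estimate_dispersion(counts, X, shrink=False)
        assert (disp < 1e-6).all()


class TestWald:
    def test_zero_coefficient_p_one(self):
        counts = pd.DataFrame(
            [[10, 10, 10, 10]], columns=[f"s{i}" for i in range(4)]
        )
        X = design_matrix(two_group_design(2), ["condition"])
        fit = fit_nb_glm(counts, X)
        res = wald_test(fit, "condition[b]")
        assert res.pvalue.iloc[0] == pytest.approx(1.0)

    def test_symmetric_in_sign(self, rng):
        counts = pd.DataFrame(
            [[10, 12, 40, 44], [40, 44, 10, 12]], columns=[f"s{i}" for i in range(4)]
        )
        X = design_matrix(two_group_design(2), ["condition"])
        fit = fit_nb_glm(counts, X, dispersions=np.full(2, 0.01))
        res = wald_test(fit, "condition[b]")
        assert res.pvalue.iloc[0] == pytest.approx(res.pvalue.iloc[1], rel=1e-9)
        assert res.log2fc.iloc[0] == pytest.approx(-res.log2fc.iloc[1], rel=1e-9)


class TestLrt:
    def test_identical_designs_give_zero_stat(self, rng):
        counts = pd.DataFrame(
            rng.poisson(30, (10, 8)), columns=[f"s{i}" for i in range(8)]
        )
        X = design_matrix(two_group_design(4), ["condition"])
        fit = fit_nb_glm(counts, X)
        with pytest.raises(ValueError, match="nested"):
            lrt_test(fit, fit)

    def test_df_is_column_difference(self, rng):
        counts = pd.DataFrame(
            rng.poisson(30, (10, 12)), columns=[f"s{i}" for i in range(12)]
        )
        design = pd.DataFrame(
            {"replicate": ["r1", "r2"] * 6,
             "time": np.repeat(["t0", "t1", "t2"], 4)},
            index=counts.columns,
        )
        Xf = design_matrix(design, ["replicate", "time"])
        Xr = design_matrix(design, ["replicate"])
        ff = fit_nb_glm(counts, Xf)
        fr = fit_nb_glm(counts, Xr, dispersions=ff.dispersion)
        res = lrt_test(ff, fr)
        assert (res.df == 2).all()
        assert (res.stat >= 0).all()

    def test_requires_shared_dispersion(self, rng):
        counts = pd.DataFrame(
            rng.poisson(30, (10, 8)), columns=[f"s{i}" for i in range(8)]
        )
        design = two_group_design(4)
        Xf = design_matrix(design, ["condition"])
        Xr = pd.DataFrame({"intercept": np.ones(8)}, index=counts.columns)
        ff = fit_nb_glm(counts, Xf, dispersions=np.full(10, 0.1))
        fr = fit_nb_glm(counts, Xr, dispersions=np.full(10, 0.5))
        with pytest.raises(ValueError, match="dispersion"):
            lrt_test(ff, fr)


class TestBH:
    def test_hand_computed_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.04]))
        np.testing.assert_allclose(out, [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.full(5, 0.03)), 0.03)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_monotone_and_order_invariant(self, ps):
        arr = np.asarray(ps)
        adj = bh_adjust(arr)
        order = np.argsort(arr)
        assert (np.diff(adj[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(len(arr))
        np.testing.assert_allclose(bh_adjust(arr[perm]), adj[perm])

    def test_nan_passthrough(self):
        out = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(out[1]) and not np.isnan(out[0])


class TestClassify:
    def test_all_insignificant_static(self):
        res = pd.DataFrame({"padj": [0.5, 0.6], "log2fc": [3.0, -3.0]})
        assert (classify(res, "loop_default") == "static").all()

    def test_threshold_enumeration(self):
        res = pd.DataFrame(
            {
                "padj": [0.04, 0.04, 0.04, 0.06, np.nan],
                "log2fc": [2.5, -2.5, 1.0, 3.0, 5.0],
            }
        )
        labels = classify(res, "gene_timepoint")
        assert list(labels) == ["up", "down", "static", "static", "static"]

    def test_partition(self, rng):
        res = pd.DataFrame(
            {"padj": rng.random(100), "log2fc": rng.normal(0, 2, 100)}
        )
        labels = classify(res, "loop_default")
        assert labels.isin(["gained", "lost", "static"]).all()
        assert len(labels) == 100

    def test_rule_presets_match_stated_thresholds(self):
        res = pd.DataFrame({"padj": [0.08], "log2fc": [1.5]})
        assert classify(res, "peak_default")[0] == "static"  # padj 0.08 >= 0.05
        assert classify(res, "peak_rad21")[0] == "increased"  # relaxed to 0.1


class TestFilter:
    def _table(self, arr):
        counts = pd.DataFrame(arr, columns=[f"s{i}" for i in range(arr.shape[1])])
        design = pd.DataFrame(
            {"condition": ["c"] * arr.shape[1]}, index=counts.columns
        )
        return CountTable(counts, design)

    def test_boundary_inclusive(self):
        # exactly 50 counts in exactly 4 samples passes
        t = self._table(np.array([[50, 50, 50, 50, 0, 0]]))
        kept, removed = filter_features(t, "gene_default")
        assert len(kept.counts) == 1 and removed == 0

    def test_below_boundary_removed(self):
        t = self._table(np.array([[50, 50, 50, 49, 0, 0]]))
        kept, removed = filter_features(t, "gene_default")
        assert len(kept.counts) == 0 and removed == 1

    def test_random_table_matches_oracle(self, rng):
        arr = rng.integers(0, 120, (200, 8))
        t = self._table(arr)
        kept, _ = filter_features(t, "gene_default")
        oracle = [i for i in range(200) if (arr[i] >= 50).sum() >= 4]
        assert list(kept.counts.index) == oracle

    def test_peak_mean_rule(self):
        t = self._table(np.array([[15, 15, 15, 15], [14, 15, 15, 15]]))
        kept, removed = filter_features(t, "peak_default")
        assert len(kept.counts) == 1 and removed == 1


class TestZscoreKmeans:
    def test_constant_feature_maps_to_zero_vector(self):
        counts = pd.DataFrame(
            [[8, 8, 8, 8, 8, 8]], columns=[f"s{i}" for i in range(6)]
        )
        design = pd.DataFrame(
            {"replicate": ["r1", "r2"] * 3, "time": np.repeat(["t0", "t1", "t2"], 2)},
            index=counts.columns,
        )
        _, _, z = zscore_kmeans(CountTable(counts, design), k=1)
        np.testing.assert_array_equal(z.iloc[0], 0.0)

    def test_archetype_recovery_and_seed_stability(self):
        truth = make_gene_truth(
            {"anchor_gained": 40, "off_anchor_transient": 40, "off_anchor_down": 40},
            seed=8,
        )
        rna = simulate_rna_counts(truth, seed=8)
        labels0, _, _ = zscore_kmeans(rna, k=3, seed=0)
        ari = adjusted_rand_score(truth.klass, labels0)
        assert ari >= 0.8
        labels1, _, _ = zscore_kmeans(rna, k=3, seed=17)
        assert adjusted_rand_score(labels0, labels1) > 0.95  # relabeling-invariant


class TestTrajectories:
    def test_all_zero_lfc(self):
        lfc = pd.DataFrame(np.zeros((10, 3)), columns=["t1", "t3", "t6"])
        classes = pd.Series(["anchor_gained"] * 10, index=lfc.index)
        medians, tests = anchor_gene_trajectories(lfc, classes)
        assert (medians.loc["anchor_gained"] == 0).all()
        assert (tests.pvalue == 1.0).all()

    def test_late_induction_significant_late_only(self):
        truth = make_gene_truth(seed=5)
        rna = simulate_rna_counts(truth, seed=5)
        X = design_matrix(rna.design, ["replicate", "time"])
        fit = fit_nb_glm(rna.counts, X)
        lfc = pd.DataFrame(
            {
                t: wald_test(fit, f"time[t{t:g}]").log2fc
                for t in (1.0, 6.0, 24.0)
            }
        )
        classes = truth.set_index("gene_id").klass
        medians, tests = anchor_gene_trajectories(lfc, classes)
        assert tests.loc[24.0, "padj"] < 0.001
        g = medians.loc["anchor_gained"]
        assert g[24.0] > g[6.0] > g[1.0] - 0.2  # rising late induction


class TestNoNormalization:
    def test_doubling_one_group_shifts_its_effect(self, rng):
        base = rng.poisson(40, (50, 8))
        counts = pd.DataFrame(base, columns=[f"s{i}" for i in range(8)])
        doubled = counts.copy()
        doubled.iloc[:, 4:] = doubled.iloc[:, 4:] * 2
        X = design_matrix(two_group_design(4), ["condition"])
        lfc0 = wald_test(fit_nb_glm(counts, X), "condition[b]").log2fc
        lfc1 = wald_test(fit_nb_glm(doubled, X), "condition[b]").log2fc
        np.testing.assert_allclose(lfc1 - lfc0, 1.0, atol=1e-6)
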