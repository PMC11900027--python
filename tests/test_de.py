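"""DE engine: filtering, normalisation, dispersion, Wald tests, BH, VST, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import beetox
from beetox.config import DESettings
from beetox.de import (
    bh_adjust,
    estimate_dispersion,
    filter_low_counts,
    fit_contrasts,
    nb_wald,
    pca,
    size_factors,
    vst_transform,
)


def counts_frame(array, prefix="s"):
    arr = np.asarray(array)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


def two_group_meta(n_per_group, treatment="clothianidin_chronic", colonies=None):
    n = 2 * n_per_group
    return pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(n)],
            "treatment": ["control"] * n_per_group + [treatment] * n_per_group,
            "compound": ["none"] * n_per_group + ["clothianidin"] * n_per_group,
            "scheme": ["none"] * n_per_group + ["chronic"] * n_per_group,
            "colony": list(range(1, n_per_group + 1)) * 2,
        }
    )


class TestFilter:
    def test_boundary_gene_retained(self):
        # exactly min_count in exactly min_samples samples -> kept (inclusive)
        row = [10] * 8 + [0] * 8
        counts = counts_frame([row, [0] * 16])
        kept = filter_low_counts(counts)
        assert list(kept.index) == ["g0"]

    def test_gene_below_count_threshold_removed(self):
        counts = counts_frame([[9] * 16])
        with pytest.warns(UserWarning):
            kept = filter_low_counts(counts)
        assert kept.empty

    @given(st.lists(st.integers(0, 20), min_size=16, max_size=16))
    @settings(max_examples=50, deadline=None)
    def test_matches_row_scan_oracle(self, row):
        counts = counts_frame([row, [50] * 16])
        kept = filter_low_counts(counts)
        expected = sum(c >= 10 for c in row) >= 8
        assert ("g0" in kept.index) == expected

    def test_order_preserved(self, small_dataset):
        _, counts, _, _ = small_dataset
        kept = filter_low_counts(counts)
        assert list(kept.index) == [g for g in counts.index if g in set(kept.index)]


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = counts_frame([[5, 5, 5], [9, 9, 9]])
        assert np.allclose(size_factors(counts), 1.0)

    def test_scaled_columns_recover_scales(self):
        # rows (2,4,8) twice: per-gene geometric mean 4, ratios 0.5/1/2
        counts = counts_frame([[2, 4, 8], [2, 4, 8]])
        assert np.allclose(size_factors(counts), [0.5, 1.0, 2.0])

    def test_single_sample_factor_one(self):
        counts = counts_frame([[7], [3]])
        assert np.allclose(size_factors(counts), 1.0)

    def test_fallback_without_allpositive_gene(self):
        counts = counts_frame([[0, 4, 8], [2, 0, 8], [2, 4, 0]])
        with pytest.warns(UserWarning, match="falling back"):
            f = size_factors(counts)
        assert (f > 0).all()

    def test_all_zero_matrix_rejected(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="all-zero"):
                size_factors(counts_frame([[0, 0], [0, 0]]))

    def test_scaling_one_sample_scales_its_relative_factor(self, rng):
        # size factors are relative: scaling one column by c multiplies its
        # factor relative to every other sample by c
        base = rng.poisson(200, size=(300, 6)) + 1
        counts = counts_frame(base)
        scaled = counts.copy()
        scaled["s0"] = scaled["s0"] * 3
        f0 = size_factors(counts)
        f1 = size_factors(scaled)
        rel0 = f0 / f0["s1"]
        rel1 = f1 / f1["s1"]
        assert rel1["s0"] / rel0["s0"] == pytest.approx(3.0, rel=1e-9)
        assert np.allclose(rel1[1:], rel0[1:])


class TestDispersion:
    def test_poisson_genes_hit_the_floor(self, rng):
        mu = 500.0
        counts = counts_frame(rng.poisson(mu, size=(1000, 14)))
        meta = two_group_meta(7)
        f = size_factors(counts)
        alpha = estimate_dispersion(counts, f, meta, include_colony=False)
        frac_floor = (alpha <= DESettings().dispersion_floor + 1e-12).mean()
        assert frac_floor >= 0.95

    def test_constant_gene_at_floor(self):
        counts = counts_frame([[50] * 14])
        meta = two_group_meta(7)
        alpha = estimate_dispersion(counts, size_factors(counts), meta, include_colony=False)
        assert alpha.iloc[0] == DESettings().dispersion_floor

    def test_nb_dispersion_recovered(self, rng):
        alpha_true = 0.2
        mu = 800.0
        y = rng.negative_binomial(1 / alpha_true, 1 / (1 + alpha_true * mu), size=(1000, 14))
        counts = counts_frame(y)
        meta = two_group_meta(7)
        alpha = estimate_dispersion(counts, size_factors(counts), meta, include_colony=False)
        assert abs(np.median(alpha) - alpha_true) / alpha_true < 0.25


class TestNBWald:
    def test_identical_groups_give_zero_lfc_unit_p(self):
        block = np.array([[120, 80, 200, 40], [30, 60, 45, 90]])
        counts = counts_frame(np.hstack([block, block]), prefix="s")
        meta = two_group_meta(4)
        res = nb_wald(counts, meta, contrast="clothianidin_chronic", include_colony=False)
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)
        assert (res["pvalue"] > 0.999).all()

    def test_matches_poisson_glm_oracle_at_floor_dispersion(self, rng):
        """Large counts at floor dispersion: Wald z within 1% of a Poisson GLM."""
        import statsmodels.api as sm

        n = 10
        mu = rng.uniform(500, 2000, size=(10, 1))
        fold = np.concatenate([np.ones(n), np.full(n, 1.3)])
        y = rng.poisson(mu * fold[None, :])
        counts = counts_frame(y)
        meta = two_group_meta(n)
        settings = DESettings(dispersion_floor=1e-8, dispersion_cap=1e-6, min_samples=4)
        factors = pd.Series(1.0, index=counts.columns)
        res = fit_contrasts(
            counts, meta, settings, contrasts=["clothianidin_chronic"],
            include_colony=False, factors=factors,
        )["clothianidin_chronic"]
        X = sm.add_constant((meta["treatment"] != "control").astype(float).to_numpy())
        for i, gene in enumerate(counts.index):
            fit = sm.GLM(y[i], X, family=sm.families.Poisson()).fit()
            z_oracle = fit.params[1] / fit.bse[1]
            assert res["wald_z"].iloc[i] == pytest.approx(z_oracle, rel=0.01)

    def test_rank_deficient_design_names_aliased_columns(self):
        counts = counts_frame(np.full((3, 6), 50))
        meta = two_group_meta(3)
        meta["colony"] = [1, 1, 1, 2, 2, 2]  # colony 2 aliases the treatment dummy
        with pytest.raises(ValueError, match="aliased.*colony"):
            nb_wald(counts, meta, contrast="clothianidin_chronic")

    def test_unknown_contrast_rejected(self, small_dataset):
        _, counts, meta, _ = small_dataset
        with pytest.raises(ValueError, match="not present"):
            nb_wald(filter_low_counts(counts), meta, contrast="imidacloprid_acute")

    def test_lfc_recovery_on_known_truth(self, small_dataset, small_de_tables):
        _, _, _, truth = small_dataset
        table = small_de_tables["clothianidin_acute"]
        genes = truth.lfc.index[truth.lfc["clothianidin_acute"] != 0].intersection(table.index)
        rho = stats.spearmanr(
            truth.lfc.loc[genes, "clothianidin_acute"], table.loc[genes, "log2fc"]
        ).statistic
        assert rho >= 0.9

    def test_scaling_a_sample_leaves_results_unchanged(self, rng):
        y = rng.negative_binomial(10, 10 / (10 + 500.0), size=(200, 12))
        counts = counts_frame(y)
        meta = two_group_meta(6)
        res1 = nb_wald(counts, meta, contrast="clothianidin_chronic", include_colony=False)
        scaled = counts.copy()
        scaled["s0"] = (scaled["s0"] * 2).astype(int)
        res2 = nb_wald(scaled, meta, contrast="clothianidin_chronic", include_colony=False)
        assert np.allclose(res1["log2fc"], res2["log2fc"], atol=0.05)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_stepup_hand_example(self):
        # p*m/rank = [.04,.04,.04,.04] after monotone enforcement
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_missing_values_propagate_and_reduce_m(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_properties_and_statsmodels_agreement(self, ps):
        from statsmodels.stats.multitest import multipletests

        out = bh_adjust(ps)
        assert (out <= 1.0 + 1e-12).all()
        assert out.min() >= min(ps) - 1e-12
        expected = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(out, expected, atol=1e-12)


class TestVST:
    def test_known_values(self):
        counts = counts_frame([[0, 7]])
        f = pd.Series([1.0, 1.0], index=counts.columns)
        out = vst_transform(counts, f)
        assert out.iloc[0, 0] == pytest.approx(0.0)
        assert out.iloc[0, 1] == pytest.approx(3.0)  # log2(8)

    def test_scaling_invariance(self):
        counts = counts_frame([[10, 20], [40, 6]])
        f1 = pd.Series([1.0, 1.0], index=counts.columns)
        doubled = counts.copy()
        doubled["s1"] = doubled["s1"] * 2
        f2 = pd.Series([1.0, 2.0], index=counts.columns)
        pd.testing.assert_frame_equal(vst_transform(counts, f1), vst_transform(doubled, f2))

    def test_nonpositive_factor_rejected(self):
        counts = counts_frame([[1, 2]])
        with pytest.raises(ValueError):
            vst_transform(counts, pd.Series([1.0, 0.0], index=counts.columns))


class TestPCA:
    def test_samples_on_a_line_load_on_pc1(self):
        base = np.array([1.0, -2.0, 0.5, 3.0])
        M = pd.DataFrame(np.outer(base, [0.0, 1.0, 2.0]))
        coords, varfrac = pca(M)
        assert varfrac[0] == pytest.approx(1.0)

    def test_identical_samples_zero_variance(self):
        M = pd.DataFrame(np.tile([[1.0], [2.0]], (1, 3)))
        coords, varfrac = pca(M)
        assert np.allclose(varfrac, 0.0)
        assert np.allclose(coords.iloc[0], coords.iloc[1])

    def test_matches_covariance_eigendecomposition(self, rng):
        M = pd.DataFrame(rng.normal(size=(5, 4)))
        coords, varfrac = pca(M)
        X = (M - M.mean(axis=1).to_numpy()[:, None]).to_numpy().T
        evals, evecs = np.linalg.eigh(X @ X.T)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(varfrac, evals / evals.sum(), atol=1e-10)
        for k in range(3):
            expected = evecs[:, k] * np.sqrt(evals[k])
            got = coords.iloc[:, k].to_numpy()
            assert np.allclose(got, expected, atol=1e-8) or np.allclose(got, -expected, atol=1e-8)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pca(pd.DataFrame([[1.0], [2.0]]))


class TestCalibration:
    def test_null_pvalues_uniform_single_seed(self):
        """Raw p-values on a fully null dataset pass a KS uniformity check."""
        cfg = beetox.SynthConfig.null(n_genes=2000, seed=0)
        counts, meta, _ = beetox.generate_counts(cfg)
        table = beetox.de_pipeline(counts, meta, contrasts=["clothianidin_acute"])[
            "clothianidin_acute"
        ]
        p = table["pvalue"].dropna().to_numpy()
        assert len(p) > 1800
        assert stats.kstest(p, "uniform").pvalue > 0.01
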