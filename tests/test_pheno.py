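"""Phenotype preparation: intervals, MICE, correlations, PCA, kinship, MLRM."""

import numpy as np
import pandas as pd
import pytest

from magicqtl.pheno import (
    average_replicates,
    correlation_matrix,
    derive_intervals,
    flag_outliers,
    kinship_matrix,
    kinship_pca,
    mice_impute,
    mlrm_fls,
    trait_pca,
)
from magicqtl.gmap import wheat_like_map
from magicqtl.simulate import (
    emit_genotypes,
    simulate_founders,
    simulate_population_mosaics,
)


def small_table(n=40, seed=0, missing=0.0):
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(
        [130, 140, 150, 172], np.array([
            [25.0, 20.0, 15.0, 20.0],
            [20.0, 25.0, 20.0, 18.0],
            [15.0, 20.0, 25.0, 15.0],
            [20.0, 18.0, 15.0, 36.0],
        ]), size=n,
    )
    df = pd.DataFrame(z, columns=["GS39", "GS55", "GS65", "FLS"])
    df.insert(0, "rep", 1)
    df.insert(0, "line_id", [f"L{i}" for i in range(n)])
    if missing:
        mask = rng.random(z.shape) < missing
        vals = df[["GS39", "GS55", "GS65", "FLS"]].to_numpy()
        vals[mask] = np.nan
        df[["GS39", "GS55", "GS65", "FLS"]] = vals
    return df


class TestDeriveIntervals:
    def test_interval_arithmetic(self):
        df = pd.DataFrame({"line_id": ["a"], "rep": [1], "GS39": [120.0],
                           "GS55": [136.0], "GS65": [146.0], "FLS": [170.0]})
        out = derive_intervals(df)
        assert out.loc[0, "d1"] == 16.0
        assert out.loc[0, "d2"] == 10.0
        assert out.loc[0, "d3"] == 34.0

    def test_missing_operand_propagates(self):
        df = pd.DataFrame({"line_id": ["a"], "rep": [1], "GS39": [np.nan],
                           "GS55": [136.0], "GS65": [146.0], "FLS": [170.0]})
        out = derive_intervals(df)
        assert np.isnan(out.loc[0, "d1"]) and out.loc[0, "d3"] == 34.0

    def test_zero_interval_boundary_and_idempotence(self):
        df = pd.DataFrame({"line_id": ["a"], "rep": [1], "GS39": [136.0],
                           "GS55": [136.0], "GS65": [140.0], "FLS": [160.0]})
        out = derive_intervals(df)
        assert out.loc[0, "d1"] == 0.0
        again = derive_intervals(out)
        pd.testing.assert_frame_equal(out, again)


class TestMiceImpute:
    def test_complete_table_unchanged(self):
        df = small_table()
        out, report = mice_impute(df, m=3, seed=1)
        pd.testing.assert_frame_equal(out, df)
        assert report.empty

    def test_observed_cells_never_altered(self):
        df = small_table(missing=0.05, seed=2)
        out, _ = mice_impute(df, m=3, seed=3)
        obs = df[["GS39", "GS55", "GS65", "FLS"]].notna()
        orig = df[["GS39", "GS55", "GS65", "FLS"]]
        new = out[["GS39", "GS55", "GS65", "FLS"]]
        assert np.allclose(orig.to_numpy()[obs.to_numpy()],
                           new.to_numpy()[obs.to_numpy()])
        assert not new.isna().to_numpy().any()

    def test_beats_marginal_mean_imputation(self):
        complete = small_table(n=300, seed=4)
        rng = np.random.default_rng(5)
        traits = ["GS39", "GS55", "GS65", "FLS"]
        masked = complete.copy()
        vals = masked[traits].to_numpy()
        mask = rng.random(vals.shape) < 0.0219
        truth = vals.copy()
        vals[mask] = np.nan
        masked[traits] = vals
        out, _ = mice_impute(masked, m=5, seed=6)
        rmse_mice = np.sqrt(np.mean(
            (out[traits].to_numpy()[mask] - truth[mask]) ** 2))
        col_means = np.nanmean(vals, axis=0)
        rmse_mean = np.sqrt(np.mean(
            (np.broadcast_to(col_means, vals.shape)[mask] - truth[mask]) ** 2))
        assert rmse_mice < rmse_mean

    def test_deterministic_under_seed(self):
        df = small_table(missing=0.05, seed=7)
        a, _ = mice_impute(df, m=5, seed=8)
        b, _ = mice_impute(df, m=5, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_fully_missing_column_rejected(self):
        df = small_table()
        df["GS39"] = np.nan
        with pytest.raises(ValueError, match="GS39"):
            mice_impute(df)


class TestCorrelationAndPCA:
    def test_self_correlation_unity_and_symmetry(self):
        R = correlation_matrix(small_table(seed=9))
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(R, R.T)

    def test_constant_column_reported_missing(self):
        df = small_table(seed=10)
        df["GS39"] = 5.0
        R = correlation_matrix(df)
        assert R.loc["GS39"].drop("GS39").isna().all()

    def test_anticorrelated_pair_sign(self):
        df = small_table(seed=11)
        df["FLS"] = 300 - df["GS39"] + np.random.default_rng(0).normal(
            0, 1, len(df))
        R = correlation_matrix(df)
        assert R.loc["FLS", "GS39"] < -0.9

    def test_two_perfectly_correlated_traits_rank_one(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=50)
        df = pd.DataFrame({"line_id": [f"L{i}" for i in range(50)], "rep": 1,
                           "GS39": x, "GS55": 2 * x + 3})
        res = trait_pca(df)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        res = trait_pca(small_table(seed=13))
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_row_order_invariance(self):
        df = small_table(seed=14)
        res1 = trait_pca(df)
        res2 = trait_pca(df.iloc[::-1].reset_index(drop=True))
        assert np.allclose(np.sort(res1.variance_fractions),
                           np.sort(res2.variance_fractions))

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="impute"):
            trait_pca(small_table(missing=0.1, seed=15))


@pytest.fixture(scope="module")
def genome_scale_population():
    gmap = wheat_like_map(markers_per_chrom=15)
    founders = simulate_founders(gmap, 8, 0.5, seed=71)
    mosaics, ids = simulate_population_mosaics(founders, gmap, 208, seed=72)
    geno = emit_genotypes(mosaics, founders, 0.005, 0.0219, seed=73,
                          line_ids=ids)
    return gmap, geno


class TestKinship:
    def test_unstructured_population_pc1_below_4_percent(
            self, genome_scale_population):
        _, geno = genome_scale_population
        res = kinship_pca(geno)
        assert res.pc1_fraction < 0.04

    def test_two_subpopulation_control_exceeds_threshold(self):
        gmap = wheat_like_map(markers_per_chrom=15)
        fA = simulate_founders(gmap, 8, 0.5, seed=74)
        fB = simulate_founders(gmap, 8, 0.5, seed=75)
        gA = emit_genotypes(*_pop(fA, gmap, 76), seed=78)
        gB = emit_genotypes(*_pop(fB, gmap, 77), seed=79)
        stacked = pd.concat([gA.to_frame(), gB.to_frame()], keys=["A", "B"])
        stacked.index = [f"L{i}" for i in range(len(stacked))]
        res = kinship_pca(stacked.fillna(1.0))
        assert res.pc1_fraction > 0.04

    def test_gram_matrix_properties(self, genome_scale_population):
        _, geno = genome_scale_population
        A = kinship_matrix(geno)
        assert np.allclose(A, A.T)
        assert (np.diag(A) >= 0).all()

    def test_monomorphic_input_rejected(self):
        df = pd.DataFrame(np.ones((10, 5)), index=[f"L{i}" for i in range(10)])
        with pytest.raises(ValueError, match="polymorphic"):
            kinship_matrix(df)


def _pop(founders, gmap, seed):
    mosaics, ids = simulate_population_mosaics(founders, gmap, 60, seed=seed)
    return mosaics, founders


class TestMLRM:
    def _table_with_planted_ffll(self, n=208, seed=16):
        rng = np.random.default_rng(seed)
        df = small_table(n=n, seed=seed)
        df["FFLL"] = 40 - 0.12 * df["FLS"] + rng.normal(0, 0.4, n)
        df["SH"] = rng.normal(52, 6, n)
        return df

    def test_planted_negative_ffll_association_flagged(self):
        df = self._table_with_planted_ffll()
        res = mlrm_fls(df)
        assert "FFLL" in res.significant
        assert res.coefficient("FFLL") < 0

    def test_pure_noise_response_rare_false_positives(self):
        rng = np.random.default_rng(17)
        n = 600
        df = pd.DataFrame(rng.normal(size=(n, 6)),
                          columns=["GS39", "GS55", "GS65", "SH", "TIL", "FEL"])
        df["FLS"] = rng.normal(size=n)
        df.insert(0, "rep", 1)
        df.insert(0, "line_id", [f"L{i}" for i in range(n)])
        res = mlrm_fls(df)
        assert len(res.significant) <= 2    # ~5% of 6 predictors expected

    def test_underdetermined_model_rejected(self):
        df = self._table_with_planted_ffll(n=6)
        with pytest.raises(ValueError, match="[Uu]nidentifiable"):
            mlrm_fls(df)

    def test_collinear_predictor_dropped(self):
        df = self._table_with_planted_ffll()
        df["GS55_copy_trait"] = df["GS55"]
        df = df.rename(columns={"GS55_copy_trait": "TIL"})
        df["TIL"] = df["GS55"]
        res = mlrm_fls(df)
        assert "TIL" in res.dropped


class TestOutliers:
    def test_extreme_value_flagged_not_altered(self):
        df = small_table(seed=18)
        df.loc[0, "GS39"] = 400.0
        qc = flag_outliers(df)
        assert ((qc["trait"] == "GS39") & (qc["row"] == 0)).any()
        assert df.loc[0, "GS39"] == 400.0


class TestReplicateAveraging:
    def test_mean_over_reps(self):
        df = pd.DataFrame({
            "line_id": ["a", "a", "b", "b"], "rep": [1, 2, 1, 2],
            "GS39": [120.0, 124.0, 130.0, np.nan],
        })
        out = average_replicates(df)
        assert out.set_index("line_id").loc["a", "GS39"] == 122.0
        assert out.set_index("line_id").loc["b", "GS39"] == 130.0
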