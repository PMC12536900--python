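import numpy as np
import pandas as pd
import pytest

from fcselect import MiConfig, MissingDataMatrix, fcs_impute, missingness_report
from fcselect.io import build_missing_data_matrix


def mcar_table(n=300, missing_rate=0.2, seed=0, r2=0.5):
    """x fully observed; w linearly related to x (R^2 = r2) with MCAR holes."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    slope = np.sqrt(r2)
    w_full = slope * x + rng.normal(0, np.sqrt(1 - r2), n)
    w = w_full.copy()
    w[rng.random(n) < missing_rate] = np.nan
    y = w_full + rng.normal(0, 1, n)
    df = pd.DataFrame({"x": x, "w": w, "y": y})
    return df, w_full


class TestMissingnessReport:
    def test_fully_observed(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        rep = missingness_report(build_missing_data_matrix(df, ["a"]))
        assert (rep["missing_rate"] == 0).all()
        assert rep.attrs["n_complete_cases"] == 2

    def test_average_rate(self):
        n = 100
        df = pd.DataFrame(
            {
                "a": np.where(np.arange(n) < 18, np.nan, 1.0),
                "b": np.where(np.arange(n) < 2, np.nan, 1.0),
                "c": np.ones(n),
            }
        )
        rep = missingness_report(build_missing_data_matrix(df, ["a", "b"]))
        assert rep.attrs["average_missing_rate"] == pytest.approx((0.18 + 0.02 + 0) / 3)

    def test_by_design_block_detected_with_threshold(self):
        n = 200
        age = np.linspace(20, 80, n)
        dep = np.ones(n)
        dep[age > 65] = np.nan  # oldest block skipped by protocol
        df = pd.DataFrame({"age": age, "dep": dep})
        rep = missingness_report(
            build_missing_data_matrix(df, ["dep"]), age_col="age"
        )
        assert bool(rep.loc["dep", "by_design"])
        assert rep.loc["dep", "by_design_threshold"] == pytest.approx(
            age[age > 65].min()
        )

    def test_mcar_not_flagged_by_design(self):
        rng = np.random.default_rng(1)
        n = 200
        age = np.linspace(20, 80, n)
        dep = np.ones(n)
        dep[rng.random(n) < 0.2] = np.nan
        df = pd.DataFrame({"age": age, "dep": dep})
        rep = missingness_report(build_missing_data_matrix(df, ["dep"]), age_col="age")
        assert not bool(rep.loc["dep", "by_design"])


class TestFcsImpute:
    def test_no_missing_data_gives_identical_copies(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((50, 3)), columns=["a", "b", "c"])
        imps = fcs_impute(
            build_missing_data_matrix(df, ["a"]), MiConfig(m=3, fcs_cycles=2, seed=0)
        )
        for t in imps.tables:
            pd.testing.assert_frame_equal(t, df)
        assert imps.between_variance["a"] == 0.0

    def test_same_seed_identical_sets(self):
        df, _ = mcar_table(seed=3)
        data = build_missing_data_matrix(df, ["w"], outcome_col="y")
        cfg = MiConfig(m=3, fcs_cycles=3, seed=9)
        a, b = fcs_impute(data, cfg), fcs_impute(data, cfg)
        for ta, tb in zip(a.tables, b.tables):
            pd.testing.assert_frame_equal(ta, tb)

    def test_observed_cells_bit_identical_across_streams(self):
        df, _ = mcar_table(seed=4)
        data = build_missing_data_matrix(df, ["w"], outcome_col="y")
        imps = fcs_impute(data, MiConfig(m=4, fcs_cycles=3, seed=1))
        obs = data.mask.to_numpy()
        for t in imps.tables:
            np.testing.assert_array_equal(
                t.to_numpy()[obs], df.to_numpy()[obs]
            )
            assert not t.isna().any().any()

    def test_proper_imputation_has_between_variance(self):
        df, _ = mcar_table(seed=5)
        data = build_missing_data_matrix(df, ["w"], outcome_col="y")
        imps = fcs_impute(data, MiConfig(m=5, fcs_cycles=3, seed=2))
        assert imps.between_variance["w"] > 0

    def test_imputed_mean_tracks_complete_data_mean(self):
        df, w_full = mcar_table(n=500, seed=6)
        data = build_missing_data_matrix(df, ["w"], outcome_col="y")
        imps = fcs_impute(data, MiConfig(m=10, fcs_cycles=5, seed=3))
        pooled_mean = np.mean([t["w"].mean() for t in imps.tables])
        se = w_full.std() / np.sqrt(len(w_full))
        assert abs(pooled_mean - w_full.mean()) < 2 * se

    def test_binary_variable_imputed_in_support(self):
        rng = np.random.default_rng(7)
        n = 300
        x = rng.standard_normal(n)
        b = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        b[rng.random(n) < 0.25] = np.nan
        df = pd.DataFrame({"x": x, "b": b})
        data = build_missing_data_matrix(df, ["b"], binary_vars=["b"])
        imps = fcs_impute(data, MiConfig(m=3, fcs_cycles=3, seed=4))
        for t in imps.tables:
            assert set(t["b"].unique()) <= {0.0, 1.0}

    def test_log1p_variable_back_transformed_nonnegative(self):
        rng = np.random.default_rng(8)
        n = 300
        x = rng.standard_normal(n)
        skew = np.exp(1.0 + 0.5 * x + rng.normal(0, 0.5, n))
        skew[rng.random(n) < 0.2] = np.nan
        df = pd.DataFrame({"x": x, "s": skew})
        data = build_missing_data_matrix(df, ["s"], log1p_vars=["s"])
        imps = fcs_impute(data, MiConfig(m=3, fcs_cycles=3, seed=5))
        for t in imps.tables:
            assert (t["s"] >= 0).all()

    def test_too_few_observed_cases_rejected(self):
        df = pd.DataFrame({"a": [1.0] * 5 + [np.nan] * 45, "b": np.arange(50.0)})
        with pytest.raises(ValueError, match="observed cases"):
            fcs_impute(build_missing_data_matrix(df, ["a"]), MiConfig(m=2, seed=0))

    def test_collinear_design_named(self):
        rng = np.random.default_rng(9)
        n = 60
        x = rng.standard_normal(n)
        w = x + rng.normal(0, 1, n)
        w[rng.random(n) < 0.2] = np.nan
        df = pd.DataFrame({"x": x, "x_copy": x, "w": w})
        with pytest.raises(ValueError, match="collinear"):
            fcs_impute(
                build_missing_data_matrix(df, ["w"]), MiConfig(m=2, fcs_cycles=1, seed=0)
            )

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError, match="m must be"):
            MiConfig(m=1)


class TestMatrixValidation:
    def test_binary_values_checked(self):
        df = pd.DataFrame({"b": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="outside"):
            MissingDataMatrix(table=df, imputable=["b"], var_types={"b": "binary"})

    def test_complete_columns_must_be_complete(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="non-imputable"):
            MissingDataMatrix(table=df, imputable=["b"])

    def test_unknown_imputable_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="not in table"):
            MissingDataMatrix(table=df, imputable=["zzz"])


def test_pooled_slope_unbiased_under_mcar():
    """Impute-then-fit recovers the complete-data regression slope (MCAR).

    Over replicates, the pooled OLS slope of y on the imputed w matches the
    slope estimated from the full data before deletion, within Monte-Carlo
    error. OLS fits come from statsmodels as an independent reference.
    """
    import statsmodels.api as sm

    n_rep = 40
    diffs = []
    for rep in range(n_rep):
        df, w_full = mcar_table(n=150, seed=100 + rep)
        full_fit = sm.OLS(df["y"], sm.add_constant(w_full)).fit()
        data = build_missing_data_matrix(df, ["w"], outcome_col="y")
        imps = fcs_impute(data, MiConfig(m=5, fcs_cycles=4, seed=rep))
        slopes = [
            sm.OLS(t["y"], sm.add_constant(t["w"])).fit().params.iloc[1]
            for t in imps.tables
        ]
        diffs.append(np.mean(slopes) - full_fit.params.iloc[1])
    bias = np.mean(diffs)
    mc_se = np.std(diffs, ddof=1) / np.sqrt(n_rep)
    assert abs(bias) < 3 * mc_se + 0.02
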