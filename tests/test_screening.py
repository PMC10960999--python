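import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson as sm_durbin_watson
import statsmodels.api as sm

from ricelwc.records import ValidationError
from ricelwc.screening import (collinearity, descriptive_stats, durbin_watson,
                               flag_outliers, normality_check, pcc_matrix,
                               select_covariates)


class TestPccMatrix:
    def test_exact_linearity_gives_unit_correlation(self):
        df = pd.DataFrame({"stage": "s", "x": [1.0, 2, 3], "y": [2.0, 4, 6]})
        r, sig = pcc_matrix(df, ["x", "y"])
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        r, _ = pcc_matrix(df, ["a", "b", "c"])
        np.testing.assert_array_equal(r.to_numpy(), r.to_numpy().T)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(1)
        fired = 0
        reps = 300
        for _ in range(reps):
            df = pd.DataFrame({"x": rng.normal(size=50), "y": rng.normal(size=50)})
            _, sig = pcc_matrix(df, ["x", "y"])
            fired += sig.loc["x", "y"] in ("*", "**")
        assert fired / reps == pytest.approx(0.05, abs=0.035)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
        df2 = df.assign(x=3.0 * df.x + 7.0)
        r1, _ = pcc_matrix(df, ["x", "y"])
        r2, _ = pcc_matrix(df2, ["x", "y"])
        assert r1.loc["x", "y"] == pytest.approx(r2.loc["x", "y"], rel=1e-12)


class TestSelectCovariates:
    def test_planted_order_recovered(self):
        rng = np.random.default_rng(3)
        n = 400
        lwc = rng.normal(0.7, 0.05, n)
        def noisy(rho, sign=1.0):
            noise = np.sqrt(1 / rho ** 2 - 1) * 0.05
            return sign * (lwc + rng.normal(0, noise, n))
        df = pd.DataFrame({"stage": "s", "LWC": lwc,
                           "strong": noisy(0.9), "mid": noisy(0.5),
                           "weak": noisy(0.1), "neg": -noisy(0.7)})
        ranked = select_covariates(df, ["strong", "mid", "weak", "neg"], k=None)
        assert list(ranked["covariate"]) == ["strong", "neg", "mid", "weak"]
        assert ranked.set_index("covariate").loc["neg", "mean_r"] < 0

    def test_top_k(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"stage": "s", "LWC": rng.normal(size=50),
                           "a": rng.normal(size=50), "b": rng.normal(size=50)})
        assert len(select_covariates(df, ["a", "b"], k=1)) == 1


class TestDescriptives:
    def test_hand_arithmetic(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        row = descriptive_stats(df, ["v"]).iloc[0]
        assert row["mean"] == 2.0 and row["sd"] == pytest.approx(1.0)
        assert row["cv"] == pytest.approx(0.5)
        assert row["max"] == 3.0 and row["min"] == 1.0

    def test_constant_column(self):
        row = descriptive_stats(pd.DataFrame({"v": [5.0] * 4}), ["v"]).iloc[0]
        assert row["sd"] == 0.0 and row["cv"] == 0.0

    def test_matches_naive_loops(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"v": rng.normal(10, 2, 100)})
        row = descriptive_stats(df, ["v"]).iloc[0]
        x = df["v"].to_numpy()
        mean = sum(x) / len(x)
        sd = (sum((xi - mean) ** 2 for xi in x) / (len(x) - 1)) ** 0.5
        assert row["mean"] == pytest.approx(mean, rel=1e-12)
        assert row["sd"] == pytest.approx(sd, rel=1e-12)


class TestOutliers:
    def test_no_flags_on_identical_data(self):
        df = pd.DataFrame({"v": [3.0] * 10})
        assert not flag_outliers(df, ["v"]).any()

    def test_planted_spike_is_the_only_flag(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"v": rng.normal(0, 1, 200)})
        df.loc[57, "v"] = 10 * df["v"].std()
        flags = flag_outliers(df, ["v"])
        assert flags.sum() == 1 and bool(flags.loc[57])

    def test_count_matches_naive_scan(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"a": rng.normal(size=500), "b": rng.standard_t(2, 500)})
        flags = flag_outliers(df, ["a", "b"])
        manual = 0
        for _, row in df.iterrows():
            hit = False
            for c in ("a", "b"):
                mu, sd = df[c].mean(), df[c].std(ddof=1)
                hit |= abs(row[c] - mu) > 3 * sd
            manual += hit
        assert flags.sum() == manual

    def test_iqr_rule_available(self):
        df = pd.DataFrame({"v": list(range(20)) + [1000]})
        assert flag_outliers(df, ["v"], rule="iqr").iloc[-1]


class TestNormality:
    def test_gaussian_rarely_rejected(self):
        rng = np.random.default_rng(8)
        rejections = sum(normality_check(rng.normal(size=200))[1] < 0.05
                         for _ in range(100))
        assert rejections <= 15

    def test_exponential_usually_rejected(self):
        rng = np.random.default_rng(9)
        rejections = sum(normality_check(rng.exponential(size=200))[1] < 0.05
                         for _ in range(50))
        assert rejections >= 45

    def test_minimal_n_runs(self):
        stat, p = normality_check([1.0, 2.0, 4.0])
        assert 0 <= stat <= 1 and 0 <= p <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            normality_check([2.0, 2.0, 2.0])


class TestCollinearity:
    def test_orthogonal_predictors_have_unit_vif(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0],
                          "b": [1, -1, 1, -1.0]})
        for row in collinearity(X):
            assert row.vif == pytest.approx(1.0, abs=1e-10)
            assert row.tolerance * row.vif == pytest.approx(1.0)

    def test_duplicated_predictor_flagged(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": x})
        rows = collinearity(X)
        assert all(r.perfect and np.isinf(r.vif) for r in rows)

    def test_matches_statsmodels_vif_oracle(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"a": rng.normal(size=60), "b": rng.normal(size=60)})
        X["c"] = 0.6 * X["a"] + rng.normal(0, 0.5, 60)
        ours = {r.predictor: r.vif for r in collinearity(X)}
        design = sm.add_constant(X)
        for j, name in enumerate(X.columns):
            ref = variance_inflation_factor(design.to_numpy(), j + 1)
            assert ours[name] == pytest.approx(ref, rel=1e-8)

    def test_tolerance_vif_product_is_one(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        for row in collinearity(X):
            assert row.tolerance * row.vif == pytest.approx(1.0, rel=1e-12)


class TestDurbinWatson:
    def test_alternating_residuals(self):
        assert durbin_watson([1, -1, 1, -1]) == pytest.approx(3.0)

    def test_constant_residuals_give_zero(self):
        assert durbin_watson([2.0, 2.0, 2.0, 2.0]) == 0.0

    def test_iid_residuals_near_two(self):
        rng = np.random.default_rng(13)
        vals = [durbin_watson(rng.normal(size=2000)) for _ in range(20)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.1)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(14)
        e = rng.normal(size=100)
        assert durbin_watson(e) == pytest.approx(sm_durbin_watson(e), rel=1e-12)

    def test_zero_residuals_rejected(self):
        with pytest.raises(ValidationError):
            durbin_watson([0.0, 0.0, 0.0])
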