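"""Random-intercept REML engine: oracles, equivariance, intervals."""

import warnings

import numpy as np
import pandas as pd
import pytest

from kpmediation import RandomInterceptLMM, normal_interval, wald_interval
from kpmediation.errors import ContractError, SingularFitError


def make_balanced(n_subj=60, m=3, tau=0.0, sigma=1.0, slope=0.8, seed=0,
                  center_clusters=False):
    rng = np.random.default_rng(seed)
    sid = np.repeat(np.arange(n_subj), m)
    x = rng.normal(size=n_subj * m)
    e = sigma * rng.normal(size=n_subj * m)
    if center_clusters:  # force the between-cluster variance to zero
        e = e - np.bincount(sid, e)[sid] / m
    u = tau * rng.normal(size=n_subj)[sid]
    y = 1.5 + slope * x + u + e
    return pd.DataFrame({"subject_id": sid.astype(str), "x": x, "y": y})


class TestAgainstClosedForms:
    def test_zero_variance_reduces_to_ols(self):
        """At the tau^2 = 0 boundary the GLS fit is exactly OLS."""
        df = make_balanced(center_clusters=True, seed=3)
        fit = RandomInterceptLMM("y", ["x"]).fit(df)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        beta = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        assert fit.random_intercept_var_ == 0.0
        assert np.abs(fit.params_.to_numpy() - beta).max() < 1e-6

    def test_matches_statsmodels_reml(self, clustered_df):
        """Independent oracle: statsmodels MixedLM on an interior fit."""
        sm = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        fit = RandomInterceptLMM("y", ["x", "z"]).fit(clustered_df)
        X = np.column_stack(
            [np.ones(len(clustered_df)), clustered_df["x"], clustered_df["z"]]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(
                clustered_df["y"].to_numpy(), X,
                groups=clustered_df["subject_id"].to_numpy(),
            ).fit(reml=True)
        assert fit.params_.to_numpy() == pytest.approx(ref.fe_params, abs=1e-6)
        assert fit.bse_.to_numpy() == pytest.approx(
            np.asarray(ref.bse_fe), rel=5e-3
        )
        assert fit.random_intercept_var_ == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), rel=1e-4
        )
        assert fit.resid_var_ == pytest.approx(ref.scale, rel=1e-4)

    def test_recovers_generating_slope(self):
        df = make_balanced(n_subj=500, tau=3.0, sigma=5.0, slope=2.0, seed=12)
        fit = RandomInterceptLMM("y", ["x"]).fit(df)
        est, se = fit.coef("x")
        assert abs(est - 2.0) < 3 * se

    def test_slope_bias_small_over_replicates(self):
        ests, ses = [], []
        for rep in range(50):
            df = make_balanced(n_subj=200, tau=2.0, sigma=3.0, slope=1.0,
                               seed=100 + rep)
            est, se = RandomInterceptLMM("y", ["x"]).fit(df).coef("x")
            ests.append(est)
            ses.append(se)
        bias = np.mean(ests) - 1.0
        assert abs(bias) < 0.05 * np.mean(ses) + 3 * np.std(ests) / np.sqrt(50)


class TestEquivariance:
    def test_response_shift_moves_only_intercept(self, clustered_df):
        f1 = RandomInterceptLMM("y", ["x", "z"]).fit(clustered_df)
        shifted = clustered_df.assign(y=clustered_df["y"] + 7.0)
        f2 = RandomInterceptLMM("y", ["x", "z"]).fit(shifted)
        assert f2.params_["Intercept"] - f1.params_["Intercept"] == pytest.approx(7.0)
        assert f2.params_["x"] == pytest.approx(f1.params_["x"])
        assert f2.params_["z"] == pytest.approx(f1.params_["z"])

    def test_record_order_invariance(self, clustered_df):
        f1 = RandomInterceptLMM("y", ["x"]).fit(clustered_df)
        f2 = RandomInterceptLMM("y", ["x"]).fit(
            clustered_df.sample(frac=1.0, random_state=9)
        )
        assert f1.params_.to_numpy() == pytest.approx(f2.params_.to_numpy())

    def test_affine_covariate_recoding_rescales_slope(self, clustered_df):
        f1 = RandomInterceptLMM("y", ["x"]).fit(clustered_df)
        recoded = clustered_df.assign(x=2.0 * clustered_df["x"] + 3.0)
        f2 = RandomInterceptLMM("y", ["x"]).fit(recoded)
        assert f2.params_["x"] == pytest.approx(f1.params_["x"] / 2.0)
        assert f2.bse_["x"] == pytest.approx(f1.bse_["x"] / 2.0)


class TestContracts:
    def test_rank_deficiency_names_aliased_term(self, clustered_df):
        df = clustered_df.assign(x_copy=clustered_df["x"])
        with pytest.raises(SingularFitError, match="x"):
            RandomInterceptLMM("y", ["x", "x_copy"]).fit(df)

    def test_listwise_deletion_counted(self, clustered_df):
        df = clustered_df.copy()
        df.loc[df.index[:10], "x"] = np.nan
        fit = RandomInterceptLMM("y", ["x"]).fit(df)
        assert fit.n_dropped_ == 10
        assert fit.n_obs_ == len(df) - 10

    def test_categorical_reference_coding(self, clustered_df):
        rng = np.random.default_rng(0)
        df = clustered_df.assign(
            sex=rng.choice(["male", "female"], len(clustered_df))
        )
        fit = RandomInterceptLMM("y", ["x", "sex"]).fit(df)
        assert "sex[female]" in fit.params_.index  # male is the reference
        assert "sex[male]" not in fit.params_.index

    def test_covariance_block_consistency(self, clustered_df):
        fit = RandomInterceptLMM("y", ["x", "z"]).fit(clustered_df)
        cov = fit.cov_params_.to_numpy()
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > 0)
        assert fit.bse_.to_numpy() == pytest.approx(np.sqrt(np.diag(cov)))


class TestWaldIntervals:
    def test_printed_example(self):
        lo, hi = normal_interval(2.45, 0.617)
        assert (lo, hi) == pytest.approx((1.24, 3.66), abs=0.01)

    def test_zero_se_degenerate(self):
        assert normal_interval(1.3, 0.0) == (1.3, 1.3)

    def test_nested_levels(self):
        lo95, hi95 = normal_interval(1.0, 0.5, 0.95)
        lo99, hi99 = normal_interval(1.0, 0.5, 0.99)
        assert lo99 < lo95 < hi95 < hi99

    def test_unknown_term_rejected(self, clustered_df):
        fit = RandomInterceptLMM("y", ["x"]).fit(clustered_df)
        with pytest.raises(ContractError):
            wald_interval(fit, "nonexistent")

    def test_matches_summary_frame(self, clustered_df):
        fit = RandomInterceptLMM("y", ["x"]).fit(clustered_df)
        lo, hi = wald_interval(fit, "x")
        row = fit.summary_frame().set_index("term").loc["x"]
        assert (lo, hi) == pytest.approx((row["ci_lower"], row["ci_upper"]))
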