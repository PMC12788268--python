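"""GLM fitting and evaluation tests, with independent ML and OLS oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from conftest import make_index_table
from jugglekit import glm, synth
from jugglekit.glm import (
    DesignSpec,
    GAMMA_LOG,
    NORMAL_IDENTITY,
    RankDeficientError,
    build_design,
    daywise_metrics,
    fit_glm,
    fit_glm_arrays,
    loso_cv,
    model_metrics,
    residual_outlier_summary,
    sensitivity_suite,
    wald_inference,
)

TABLE2_BETA = np.array([2.5563, 0.4073, 0.1669, 0.5279])


def direct_ml_gamma_log(X, y):
    """Oracle: maximize the Gamma log-link likelihood over beta directly.

    For the log link the ML equations for beta do not involve the shape
    parameter, so the oracle maximizes sum(-log mu - y/mu) with BFGS.
    """

    def nll(beta):
        mu = np.exp(X @ beta)
        return float(np.sum(np.log(mu) + y / mu))

    def grad(beta):
        mu = np.exp(X @ beta)
        return X.T @ (1.0 - y / mu)

    start = np.linalg.lstsq(X, np.log(y), rcond=None)[0]
    res = optimize.minimize(nll, start, jac=grad, method="BFGS", options={"gtol": 1e-12})
    return res.x


class TestGammaLogFit:
    def test_intercept_only_is_log_mean(self):
        y = np.random.default_rng(0).gamma(2.0, 3.0, size=200)
        fit = fit_glm_arrays(np.ones((len(y), 1)), y, family=GAMMA_LOG)
        assert fit.beta[0] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_parameter_recovery_at_n2000(self):
        rng = np.random.default_rng(42)
        df = make_index_table(2000, rng)
        fit = fit_glm(DesignSpec(), df)
        assert np.abs(fit.beta - TABLE2_BETA).max() < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_ml_oracle_on_small_fixture(self, seed):
        rng = np.random.default_rng(seed)
        df = make_index_table(30, rng)
        X, y, _ = build_design(df, DesignSpec())
        fit = fit_glm_arrays(X, y, family=GAMMA_LOG)
        oracle = direct_ml_gamma_log(X, y)
        assert np.abs(fit.beta - oracle).max() < 1e-6

    def test_matches_statsmodels_coefficients_and_se(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        df = make_index_table(150, rng)
        X, y, _ = build_design(df, DesignSpec())
        fit = fit_glm_arrays(X, y, family=GAMMA_LOG)
        ref = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit(
            tol=1e-14
        )
        assert np.abs(fit.beta - ref.params).max() < 1e-7
        assert np.abs(fit.se - ref.bse).max() < 1e-7
        assert fit.dispersion == pytest.approx(ref.scale, rel=1e-8)

    def test_predictions_strictly_positive(self):
        rng = np.random.default_rng(9)
        df = make_index_table(100, rng)
        fit = fit_glm(DesignSpec(), df)
        extreme = np.array([[1.0, -50.0, 40.0, -30.0]])
        assert fit.predict(extreme) > 0

    def test_non_positive_response_rejected(self):
        with pytest.raises(ValueError):
            fit_glm_arrays(np.ones((5, 1)), np.array([1.0, 2, 0, 3, 4]), family=GAMMA_LOG)

    def test_rank_deficiency_is_distinct_error(self):
        X = np.ones((10, 2))
        with pytest.raises(RankDeficientError):
            fit_glm_arrays(X, np.ones(10), family=GAMMA_LOG)


class TestNormalIdentityFit:
    def test_equals_closed_form_least_squares(self):
        rng = np.random.default_rng(3)
        df = make_index_table(60, rng)
        X, y, _ = build_design(df, DesignSpec())
        fit = fit_glm_arrays(X, y, family=NORMAL_IDENTITY)
        closed = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.abs(fit.beta - closed).max() < 1e-10


class TestWaldInference:
    def test_reference_worked_example(self):
        # beta = 0.5279, SE = 0.1036 -> CI [0.325, 0.731], exp(beta) = 1.695
        fit = glm.GLMFit(
            family=GAMMA_LOG,
            beta=np.array([0.5279]),
            se=np.array([0.1036]),
            cov_beta=np.array([[0.1036**2]]),
            dispersion=1.0,
            dispersion_ml=1.0,
            loglik=0.0,
            n=57,
            k=1,
            names=["Z_S"],
            converged=True,
            n_iter=1,
        )
        table = wald_inference(fit)
        assert round(table.loc["Z_S", "ci_low"], 3) == 0.325
        assert round(table.loc["Z_S", "ci_high"], 3) == 0.731
        assert round(table.loc["Z_S", "exp_beta"], 3) == 1.695

    def test_zero_coefficient_gives_unit_effect(self):
        fit = glm.GLMFit(
            family=GAMMA_LOG,
            beta=np.array([0.0]),
            se=np.array([0.2]),
            cov_beta=np.array([[0.04]]),
            dispersion=1.0,
            dispersion_ml=1.0,
            loglik=0.0,
            n=10,
            k=1,
            names=["x"],
            converged=True,
            n_iter=1,
        )
        table = wald_inference(fit)
        assert table.loc["x", "exp_beta"] == 1.0
        assert table.loc["x", "ci_low"] == -table.loc["x", "ci_high"]


class TestMetrics:
    def test_aic_from_loglik_and_k(self):
        fit = glm.GLMFit(
            family=GAMMA_LOG,
            beta=np.zeros(4),
            se=np.ones(4),
            cov_beta=np.eye(4),
            dispersion=1.0,
            dispersion_ml=1.0,
            loglik=-188.63,
            n=57,
            k=4,
            names=list("abcd"),
            converged=True,
            n_iter=1,
        )
        assert fit.aic == pytest.approx(385.26)

    def test_cox_snell_zero_when_model_adds_nothing(self):
        # intercept-only "model": LL1 equals the null LL0, so pseudo-R2 is 0
        y = np.random.default_rng(1).gamma(2.0, 2.0, 80)
        df = pd.DataFrame({"Perf": y})
        spec = DesignSpec(predictors=())
        fit = fit_glm(spec, df)
        report = model_metrics(fit, spec, df)
        assert report.pseudo_r2_cs == pytest.approx(0.0, abs=1e-9)

    def test_perfect_predictions_metrics(self):
        rng = np.random.default_rng(6)
        df = make_index_table(80, rng, dispersion=1e-8)
        fit = fit_glm(DesignSpec(), df)
        report = model_metrics(fit, DesignSpec(), df)
        assert report.r2 > 0.9999
        assert report.rmse < 0.01 * df["Perf"].mean()
        assert report.rmse >= report.mae >= 0.0


class TestLoso:
    def test_near_noiseless_generalizes(self):
        rng = np.random.default_rng(7)
        df = make_index_table(57, rng, dispersion=1e-6)
        out = loso_cv(DesignSpec(), df)
        assert out["r2"] >= 0.95

    def test_null_response_does_not_generalize(self):
        r2s = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            df = make_index_table(57, rng, beta=(2.5563, 0.0, 0.0, 0.0))
            r2s.append(loso_cv(DesignSpec(), df)["r2"])
        assert np.mean(r2s) <= 0.0

    def test_two_participants_rejected(self):
        rng = np.random.default_rng(8)
        df = make_index_table(12, rng, n_participants=2)
        with pytest.raises(ValueError):
            loso_cv(DesignSpec(), df)


class TestDaywise:
    def test_constant_day_floored_at_zero(self):
        rng = np.random.default_rng(10)
        df = make_index_table(60, rng)
        df.loc[df["day"] == 1, "Perf"] = 5.0
        fit = fit_glm(DesignSpec(), df)
        by_day = daywise_metrics(fit, DesignSpec(), df).set_index("day")
        assert by_day.loc[1, "r2"] == 0.0
        assert bool(by_day.loc[1, "r2_floored"])

    def test_stronger_days_fit_better(self):
        rng = np.random.default_rng(11)
        df = make_index_table(300, rng)
        # inflate the noise on day 1 only: signal-to-noise rises with day
        d1 = df["day"] == 1
        df.loc[d1, "Perf"] = rng.gamma(0.2, df.loc[d1, "Perf"] / 0.2)
        fit = fit_glm(DesignSpec(), df)
        by_day = daywise_metrics(fit, DesignSpec(), df).set_index("day")
        assert by_day.loc[1, "r2"] < by_day.loc[5, "r2"]
        assert by_day.loc[1, "r2"] < by_day.loc[10, "r2"]


class TestResidualSummary:
    def test_hand_computed_cutoff(self):
        rng = np.random.default_rng(12)
        df = make_index_table(10, rng)
        df["Perf"] = np.arange(1.0, 11.0)
        fit = fit_glm(DesignSpec(), df)
        out = residual_outlier_summary(fit, DesignSpec(), df)
        assert out["cutoff"] == pytest.approx(5.5 + 3 * 1.4826 * 2.5)
        assert out["n_excluded"] == 0

    def test_extreme_value_excluded(self):
        rng = np.random.default_rng(13)
        df = make_index_table(30, rng)
        df["Perf"] = np.r_[np.full(29, 5.0) + rng.uniform(0, 1, 29), 1000.0]
        fit = fit_glm(DesignSpec(), df)
        out = residual_outlier_summary(fit, DesignSpec(), df)
        assert out["n_excluded"] == 1


class TestSensitivity:
    def test_suite_reports_all_models(self):
        rng = np.random.default_rng(14)
        df = make_index_table(57, rng)
        full = make_index_table(60, rng)
        full.loc[full.index[:3], "Z_S"] = np.nan
        out = sensitivity_suite(df, full_data=full)
        assert len(out) == 5
        assert (out["error"] == "").all()
        base_aic = out.loc[out["model"] == "base", "aic"].item()
        assert np.isfinite(base_aic)

    def test_participant_intercepts_help_with_heterogeneity(self):
        rng = np.random.default_rng(15)
        df = make_index_table(120, rng, n_participants=12)
        offsets = dict(zip(range(1, 13), rng.normal(0, 1.0, 12)))
        df["Perf"] *= np.exp(df["participant"].map(offsets))
        out = sensitivity_suite(df).set_index("model")
        assert (
            out.loc["base + interactions + Day + subject", "aic"]
            < out.loc["base", "aic"]
        )

    def test_noise_interactions_rarely_improve_aic(self):
        improvements = 0
        for seed in range(60):
            rng = np.random.default_rng(2000 + seed)
            df = make_index_table(57, rng)
            base = fit_glm(DesignSpec(), df)
            inter = fit_glm(
                DesignSpec(interactions=(("Z_P", "Z_A"), ("Z_P", "Z_S"), ("Z_A", "Z_S"))),
                df,
            )
            if base.aic - inter.aic > 2.0:
                improvements += 1
        assert improvements <= 15  # pure-noise interactions seldom earn their AIC cost
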