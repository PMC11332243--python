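"""Mixed-model estimation: oracles, limiting cases, inference helpers."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from thermocontrast import (
    ModelSpec,
    SeparationError,
    fit_linear_mixed,
    fit_logistic_mixed,
    omnibus_interaction_test,
    pairwise_contrasts,
    power_simulation,
    qst_control_model,
)


def _simulate_logistic(n_groups, per_group, beta, sigma_u, rng):
    """Direct model-based simulation, independent of the study generator."""
    x = rng.normal(0.0, 1.0, n_groups * per_group)
    g = np.repeat(np.arange(n_groups), per_group)
    u = rng.normal(0.0, sigma_u, n_groups) if sigma_u > 0 else np.zeros(n_groups)
    eta = beta[0] + beta[1] * x + u[g]
    y = (rng.random(len(x)) < expit(eta)).astype(int)
    return pd.DataFrame({"y": y, "x": x, "participant_id": [f"G{i}" for i in g]})


SPEC_XY = ModelSpec(formula="y ~ x")


class TestLogisticMixed:
    def test_sigma_zero_matches_irls_oracle(self, rng):
        # with the random-intercept SD pinned at 0 the model is ordinary
        # logistic regression; statsmodels GLM (IRLS) is the oracle
        for _ in range(5):
            data = _simulate_logistic(30, 12, (-1.0, 0.8), 0.0, rng)
            fit = fit_logistic_mixed(SPEC_XY, data, sigma_u=0.0)
            oracle = sm.GLM(
                data.y, sm.add_constant(data.x), family=sm.families.Binomial()
            ).fit()
            np.testing.assert_allclose(
                fit.params.to_numpy(), oracle.params.to_numpy(), atol=1e-4
            )
            assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)

    def test_matches_lme4_glmer(self, model_table, tmp_path):
        """Cross-check the Laplace fit against R lme4 on real generator output."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        cols = model_table[["phs", "innocuous_log10_tcf", "participant_id"]]
        csv = tmp_path / "tab.csv"
        cols.to_csv(csv, index=False)
        script = (
            'suppressMessages(library(lme4));'
            f'd <- read.csv("{csv}");'
            'm <- glmer(phs ~ innocuous_log10_tcf + (1|participant_id), d, family=binomial);'
            'cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = [float(v) for v in out.stdout.strip().splitlines()]
        fit = fit_logistic_mixed(
            ModelSpec(formula="phs ~ innocuous_log10_tcf"), model_table
        )
        np.testing.assert_allclose(fit.params.to_numpy(), ref[:2], atol=2e-3)
        assert fit.random_intercept_sd == pytest.approx(ref[2], abs=5e-3)
        assert fit.loglik == pytest.approx(ref[3], abs=1e-2)

    def test_constant_response_raises(self):
        data = pd.DataFrame(
            {"y": np.zeros(40), "x": np.arange(40.0), "participant_id": ["a", "b"] * 20}
        )
        with pytest.raises(SeparationError):
            fit_logistic_mixed(SPEC_XY, data)

    def test_complete_separation_raises(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        data = pd.DataFrame(
            {"y": (x > 0.5).astype(int), "x": x, "participant_id": ["a", "b"] * 20}
        )
        with pytest.raises(SeparationError):
            fit_logistic_mixed(SPEC_XY, data, sigma_u=0.0)

    def test_rank_deficient_design_raises(self, model_table):
        data = model_table.assign(dup=model_table.innocuous_log10_tcf)
        with pytest.raises(ValueError, match="rank"):
            fit_logistic_mixed(
                ModelSpec(formula="phs ~ innocuous_log10_tcf + dup"), data
            )

    def test_quadrature_refinement_converges(self, rng):
        data = _simulate_logistic(60, 9, (-1.5, 1.0), 1.0, rng)
        b15 = fit_logistic_mixed(SPEC_XY, data, n_quad=15).params.to_numpy()
        b25 = fit_logistic_mixed(SPEC_XY, data, n_quad=25).params.to_numpy()
        b1 = fit_logistic_mixed(SPEC_XY, data, n_quad=1).params.to_numpy()
        assert np.max(np.abs(b25 - b15)) < 1e-3
        assert np.max(np.abs(b25 - b15)) <= np.max(np.abs(b25 - b1)) + 1e-12

    def test_aic_identity(self, rng):
        data = _simulate_logistic(40, 9, (-1.0, 0.5), 0.8, rng)
        fit = fit_logistic_mixed(SPEC_XY, data)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
        assert fit.n_params == 3  # intercept, slope, sigma_u

    def test_odds_ratios_are_exponentiated_coefficients(self, rng):
        data = _simulate_logistic(40, 9, (-1.0, 0.5), 0.5, rng)
        fit = fit_logistic_mixed(SPEC_XY, data)
        np.testing.assert_allclose(
            fit.odds_ratios["or"], np.exp(fit.params), rtol=1e-12
        )


class TestLinearMixed:
    def test_no_cluster_variance_matches_ols(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.5, n)
        data = pd.DataFrame(
            {"y": y, "x": x, "participant_id": np.repeat(np.arange(30), 10)}
        )
        fit = fit_linear_mixed(ModelSpec(formula="y ~ x", family="gaussian"), data)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params, atol=1e-5)
        assert fit.singular or fit.random_intercept_sd < 0.1

    def test_known_condition_shift_recovered(self, rng):
        # balanced two-condition design with a 1.0 degC true shift
        n_sub = 80
        u = rng.normal(0, 1.0, n_sub)
        rows = []
        for i in range(n_sub):
            for cond in (0.0, 1.0):
                for _ in range(3):
                    rows.append(
                        {
                            "y": 28.0 + 1.0 * cond + u[i] + rng.normal(0, 0.8),
                            "cond": cond,
                            "participant_id": i,
                        }
                    )
        data = pd.DataFrame(rows)
        fit = fit_linear_mixed(ModelSpec(formula="y ~ cond", family="gaussian"), data)
        assert fit.params["cond"] == pytest.approx(1.0, abs=0.15)
        assert fit.random_intercept_sd == pytest.approx(1.0, abs=0.3)

    def test_aic_identity_and_reml_flag(self, analysis_tables):
        analysis, _, _ = analysis_tables
        sub = analysis[analysis.task == "innocuous"]
        spec = ModelSpec(
            formula="t_cold_c ~ C(contrast_condition, Treatment(32)) + trial_index",
            family="gaussian",
        )
        fit = fit_linear_mixed(spec, sub)
        assert fit.method == "reml"
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
        ml = fit_linear_mixed(spec, sub, reml=False)
        assert ml.method == "ml"
        assert ml.loglik >= fit.loglik - 50  # both finite, sane


class TestOmnibus:
    def test_identical_specs_give_zero(self, model_table):
        spec = ModelSpec(formula="phs ~ innocuous_log10_tcf")
        fit = fit_logistic_mixed(spec, model_table)
        chi2, df, p = omnibus_interaction_test(fit, fit)
        assert (chi2, df, p) == (0.0, 0, 1.0)

    def test_df_bookkeeping_for_interaction(self, analysis_tables):
        analysis, _, _ = analysis_tables
        both = analysis.assign(phs=analysis.phs.astype(int))
        full = fit_logistic_mixed(
            ModelSpec(formula="phs ~ C(contrast_condition) * task"), both
        )
        reduced = fit_logistic_mixed(
            ModelSpec(formula="phs ~ C(contrast_condition) + task"), both
        )
        chi2, df, p = omnibus_interaction_test(full, reduced)
        assert df == 2
        assert chi2 >= 0.0
        assert 0.0 <= p <= 1.0

    def test_reml_fits_rejected(self, analysis_tables):
        analysis, _, _ = analysis_tables
        sub = analysis[analysis.task == "innocuous"]
        full = fit_linear_mixed(
            ModelSpec(formula="t_cold_c ~ C(contrast_condition)", family="gaussian"), sub
        )
        reduced = fit_linear_mixed(
            ModelSpec(formula="t_cold_c ~ 1", family="gaussian"), sub
        )
        with pytest.raises(ValueError, match="reml"):
            omnibus_interaction_test(full, reduced)


class TestPairwiseContrasts:
    def test_three_level_factor_additivity(self, analysis_tables):
        analysis, _, _ = analysis_tables
        both = analysis.assign(phs=analysis.phs.astype(int))
        fit = fit_logistic_mixed(
            ModelSpec(formula="phs ~ C(contrast_condition, Treatment(32)) * task"), both
        )
        contrasts = {c.pair: c for c in pairwise_contrasts(fit, "contrast_condition")}
        assert len(contrasts) == 3
        est = {p: c.estimate for p, c in contrasts.items()}
        # (38-32) + (44-38) == (44-32) exactly, by linearity
        assert est["38 - 32"] + est["44 - 38"] == pytest.approx(est["44 - 32"])
        for c in contrasts.values():
            assert c.adjusted_p >= c.p_value - 1e-12
            assert c.adjustment == "tukey"

    def test_two_level_factor_equals_coefficient(self, analysis_tables):
        analysis, _, _ = analysis_tables
        both = analysis.assign(phs=analysis.phs.astype(int))
        fit = fit_logistic_mixed(ModelSpec(formula="phs ~ task"), both)
        (c,) = pairwise_contrasts(fit, "task")
        name = [n for n in fit.params.index if "task" in n][0]
        assert abs(c.estimate) == pytest.approx(abs(fit.params[name]))

    def test_absent_factor_raises(self, model_table):
        fit = fit_logistic_mixed(ModelSpec(formula="phs ~ innocuous_log10_tcf"), model_table)
        with pytest.raises(ValueError):
            pairwise_contrasts(fit, "contrast_condition")


class TestQSTControl:
    def test_null_qst_covariates_not_significant(self, medium_dataset, analysis_tables, model_table):
        # QST thresholds are generated independently of PHS: no tiny p-values
        fit = qst_control_model(medium_dataset.participants, model_table)
        assert fit.n_obs == len(model_table)
        assert (fit.p_values[1:] > 1e-4).all()

    def test_duplicated_covariate_raises(self, medium_dataset, model_table):
        participants = medium_dataset.participants.copy()
        participants["qst_warm_detection"] = participants["qst_cold_detection"]
        with pytest.raises(ValueError, match="rank"):
            qst_control_model(participants, model_table)

    def test_missing_covariate_raises(self, medium_dataset, model_table):
        with pytest.raises(ValueError, match="qst_heat_pain"):
            qst_control_model(
                medium_dataset.participants.drop(columns="qst_heat_pain"), model_table
            )


class TestPowerSimulation:
    def test_null_effect_power_near_alpha(self):
        res = power_simulation(
            100, 4, odds_ratio=1.0, baseline_rate=0.2, reps=400, seed=5
        )
        assert res.ci_low <= 0.05 <= res.ci_high + 0.02
        assert res.power < 0.12

    def test_power_monotone_in_odds_ratio(self):
        powers = [
            power_simulation(
                80, 4, odds_ratio=orr, baseline_rate=0.15, reps=150, seed=9
            ).power
            for orr in (1.2, 1.5, 2.0)
        ]
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[2] > powers[0]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            power_simulation(10, 2, 1.5, "weibull", baseline_rate=0.2, reps=200)
        with pytest.raises(ValueError):
            power_simulation(10, 2, 1.5, baseline_rate=0.2, reps=10)
        with pytest.raises(ValueError):
            power_simulation(10, 2, 1.5, baseline_rate=1.5, reps=200)
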