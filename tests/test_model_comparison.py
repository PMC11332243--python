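"""ROC/AUC, bootstrap resampling and candidate-model ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from thermocontrast import (
    MixedModelFit,
    ModelSpec,
    bootstrap_model_auc,
    candidate_phs_specs,
    compare_models,
    fit_logistic_mixed,
    marginal_effects,
    roc_auc,
)
from thermocontrast.model_comparison import _resample_indices


def mann_whitney_auc(scores, labels):
    """Exhaustive pairwise oracle: wins + half-ties over all pos/neg pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    diff = pos[:, None] - neg[None, :]
    return (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg))


class TestROCAUC:
    def test_perfect_separation(self):
        curve = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert curve.auc == 1.0

    def test_hand_worked_example(self):
        # pairs: (.35,.1)+, (.35,.4)-, (.8,.1)+, (.8,.4)+ => 3/4
        curve = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert curve.auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.random(500)
        labels = rng.random(500) < 0.3
        curve = roc_auc(scores, labels)
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.thresholds) <= 0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_null_scores_give_half(self, rng):
        scores = rng.random(10_000)
        labels = rng.random(10_000) < 0.5
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_matches_mann_whitney_oracle_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 200))
            scores = rng.integers(0, 8, n) / 7.0  # heavy ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )


class TestResampling:
    def test_row_resample_size(self, model_table, rng):
        idx = _resample_indices(model_table, "row", "participant_id", rng)
        assert len(idx) == len(model_table)

    def test_participant_resample_keeps_participants_whole(self, model_table, rng):
        idx = _resample_indices(model_table, "participant", "participant_id", rng)
        resampled = model_table.iloc[idx]
        # every drawn participant contributes their full 9-trial block
        sizes = resampled.groupby("participant_id").size()
        assert (sizes % 9 == 0).all()
        assert len(idx) == len(model_table)  # balanced design preserves size

    def test_unknown_unit_raises(self, model_table, rng):
        with pytest.raises(ValueError):
            _resample_indices(model_table, "block", "participant_id", rng)


class TestBootstrapAUC:
    def test_intercept_only_ci_contains_half(self, model_table):
        res = bootstrap_model_auc(
            ModelSpec(formula="phs ~ 1"), model_table, n_reps=60, seed=4
        )
        assert res.ci_low <= 0.5 <= res.ci_high

    def test_deterministic_given_seed(self, model_table):
        spec = ModelSpec(formula="phs ~ innocuous_log10_tcf")
        a = bootstrap_model_auc(spec, model_table, n_reps=30, seed=77)
        b = bootstrap_model_auc(spec, model_table, n_reps=30, seed=77)
        assert a.ci_low == b.ci_low and a.ci_high == b.ci_high
        np.testing.assert_array_equal(a.replicate_aucs, b.replicate_aucs)

    def test_replicates_recorded(self, model_table):
        spec = ModelSpec(formula="phs ~ innocuous_log10_tcf")
        res = bootstrap_model_auc(spec, model_table, n_reps=30, seed=3)
        assert res.n_reps + res.n_failed == 30
        assert np.all((res.replicate_aucs >= 0) & (res.replicate_aucs <= 1))
        assert res.ci_low <= np.median(res.replicate_aucs) <= res.ci_high

    def test_ci_width_shrinks_with_more_reps(self, model_table):
        spec = ModelSpec(formula="phs ~ innocuous_log10_tcf")
        wide = bootstrap_model_auc(spec, model_table, n_reps=25, seed=1)
        narrow = bootstrap_model_auc(spec, model_table, n_reps=150, seed=1)
        assert (narrow.ci_high - narrow.ci_low) <= (wide.ci_high - wide.ci_low) * 1.5


class TestCompareModels:
    def test_four_candidates_ranked(self, model_table):
        table, results = compare_models(
            candidate_phs_specs(), model_table, n_reps=0, seed=0
        )
        assert len(table) == 4
        assert list(table["rank"]) == [1, 2, 3, 4]
        assert table.point_auc.is_monotonic_decreasing or (
            table.point_auc.round(12).is_monotonic_decreasing
        )

    def test_duplicate_specs_tie_broken_by_input_order(self, model_table):
        specs = [
            ModelSpec(formula="phs ~ innocuous_log10_tcf", name="first"),
            ModelSpec(formula="phs ~ innocuous_log10_tcf", name="second"),
        ]
        table, _ = compare_models(specs, model_table, n_reps=0, seed=0)
        assert table.point_auc.nunique() == 1
        assert list(table.model) == ["first", "second"]

    def test_mismatched_responses_raise(self, model_table):
        specs = [
            ModelSpec(formula="phs ~ innocuous_log10_tcf"),
            ModelSpec(formula="trial_index ~ innocuous_log10_tcf"),
        ]
        with pytest.raises(ValueError):
            compare_models(specs, model_table, n_reps=0)


class TestMarginalEffects:
    def test_zero_coefficients_give_flat_half(self, model_table):
        fit = fit_logistic_mixed(
            ModelSpec(formula="phs ~ innocuous_log10_tcf"), model_table
        )
        fit.params[:] = 0.0
        me = marginal_effects(fit, "innocuous_log10_tcf", np.linspace(-1.2, -0.6, 9))
        np.testing.assert_allclose(me.prob, 0.5)

    def test_monotone_in_positive_coefficient(self, model_table):
        fit = fit_logistic_mixed(
            ModelSpec(formula="phs ~ innocuous_log10_tcf"), model_table
        )
        assert fit.params["innocuous_log10_tcf"] > 0
        x = model_table.innocuous_log10_tcf
        me = marginal_effects(fit, "innocuous_log10_tcf", np.linspace(x.min(), x.max(), 25))
        assert me.prob.is_monotonic_increasing
        assert ((me.ci_low <= me.prob) & (me.prob <= me.ci_high)).all()

    def test_out_of_range_grid_warns(self, model_table):
        fit = fit_logistic_mixed(
            ModelSpec(formula="phs ~ innocuous_log10_tcf"), model_table
        )
        with pytest.warns(UserWarning, match="outside"):
            marginal_effects(fit, "innocuous_log10_tcf", [5.0])

    def test_calibration_near_observed_rate(self, model_table):
        # predictions at the observed predictor values average near the
        # observed PHS rate (fixed effects only, well-specified simulation)
        fit = fit_logistic_mixed(
            ModelSpec(formula="phs ~ innocuous_log10_tcf"), model_table
        )
        me = marginal_effects(
            fit, "innocuous_log10_tcf", model_table.innocuous_log10_tcf.to_numpy()
        )
        assert me.prob.mean() == pytest.approx(model_table.phs.mean(), abs=0.05)

    def test_unknown_predictor_raises(self, model_table):
        fit = fit_logistic_mixed(
            ModelSpec(formula="phs ~ innocuous_log10_tcf"), model_table
        )
        with pytest.raises(ValueError):
            marginal_effects(fit, "nonexistent", [0.0])
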