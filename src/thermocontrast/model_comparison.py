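"""ROC/AUC model comparison with bootstrapped train/test resampling.

Candidate PHS models are compared by how well their predicted probabilities
rank PHS over non-PHS trials (area under the ROC curve) and by AIC.
Uncertainty around each AUC comes from a paired-resample bootstrap: per
replicate, a training set and a test set are drawn independently with
replacement, each of the original size; the model is refit on the training
set and its AUC measured on the test set; the 95% interval is the 2.5/97.5
percentile of the replicate AUCs.  Test-set scores use the fixed effects
only (random intercept 0), since resampled test rows can involve
participants unseen in training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy.special import expit
from scipy.stats import norm
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .mixed_models import MixedModelFit, ModelSpec, SeparationError, fit_logistic_mixed

__all__ = [
    "ROCCurve",
    "BootstrapAUCResult",
    "roc_auc",
    "predict_fixed",
    "bootstrap_model_auc",
    "compare_models",
    "candidate_phs_specs",
    "marginal_effects",
]


@dataclass
class ROCCurve:
    """ROC curve: descending thresholds with cumulative false/true positive
    rates and the trapezoidal area under the curve."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class BootstrapAUCResult:
    """Point AUC plus the bootstrap replicate distribution and its 95%
    percentile interval.  ``n_failed`` counts dropped (non-converged or
    degenerate) replicates."""

    point_auc: float
    replicate_aucs: np.ndarray
    ci_low: float
    ci_high: float
    n_reps: int
    n_failed: int
    resampling_unit: str
    seed: int | None
    point_curve: ROCCurve = field(repr=False, default=None)
    fit: MixedModelFit = field(repr=False, default=None)


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and trapezoidal AUC of scores against boolean labels.

    Ties in scores step the curve diagonally (equivalent to the
    tie-corrected Mann-Whitney estimator).  Requires at least one positive
    and one negative label.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("labels contain a single class; AUC undefined")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


def predict_fixed(fit: MixedModelFit, data: pd.DataFrame) -> np.ndarray:
    """Predicted probabilities from the fixed effects only (u_i = 0)."""
    (X,) = patsy.build_design_matrices([fit.design_info], data, return_type="dataframe")
    return expit(np.asarray(X) @ fit.params.to_numpy())


def _resample_indices(data: pd.DataFrame, unit: str, group_col: str, rng) -> np.ndarray:
    n = len(data)
    if unit == "row":
        return rng.integers(0, n, n)
    if unit == "participant":
        codes, uniques = pd.factorize(data[group_col])
        order = np.argsort(codes, kind="stable")
        # row positions of each participant, participants drawn with
        # replacement: a drawn participant contributes all of their rows
        bounds = np.searchsorted(codes[order], np.arange(len(uniques) + 1))
        drawn = rng.integers(0, len(uniques), len(uniques))
        return np.concatenate([order[bounds[d] : bounds[d + 1]] for d in drawn])
    raise ValueError(f"unknown resampling unit {unit!r}")


def bootstrap_model_auc(
    spec: ModelSpec,
    data: pd.DataFrame,
    n_reps: int = 2000,
    resampling_unit: str = "row",
    seed: int | None = None,
    n_quad: int = 1,
    max_failure_fraction: float = 0.10,
) -> BootstrapAUCResult:
    """Bootstrap the AUC of one candidate model.

    The model must fit on the full data (this gives the point AUC).  Per
    replicate, independent with-replacement training and test resamples of
    the original size are drawn (by row, or by participant keeping each
    participant's trials together); the model is refit on the training set
    and scored on the test set with fixed effects only.  Replicates whose
    fit fails or whose test labels are single-class are dropped and counted;
    more than ``max_failure_fraction`` failures is an error.

    Deterministic given ``seed``.  ``n_reps=0`` skips the bootstrap and
    returns the point AUC alone.
    """
    full_fit = fit_logistic_mixed(spec, data, n_quad=n_quad)
    y = data[spec.response].to_numpy().astype(int)
    point_curve = roc_auc(predict_fixed(full_fit, data), y)
    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    n_failed = 0
    for _ in range(n_reps):
        train_idx = _resample_indices(data, resampling_unit, spec.groups, rng)
        test_idx = _resample_indices(data, resampling_unit, spec.groups, rng)
        train = data.iloc[train_idx]
        test = data.iloc[test_idx]
        try:
            fit = fit_logistic_mixed(spec, train, n_quad=n_quad)
            if not fit.converged:
                raise RuntimeError("replicate fit did not converge")
            aucs.append(roc_auc(predict_fixed(fit, test), test[spec.response]).auc)
        except (SeparationError, RuntimeError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if n_reps > 0 and n_failed > max_failure_fraction * n_reps:
        raise RuntimeError(
            f"{n_failed}/{n_reps} bootstrap replicates failed "
            f"(> {max_failure_fraction:.0%})"
        )
    arr = np.asarray(aucs)
    if len(arr):
        ci_low, ci_high = np.percentile(arr, [2.5, 97.5])
    else:
        ci_low = ci_high = np.nan
    return BootstrapAUCResult(
        point_auc=point_curve.auc,
        replicate_aucs=arr,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_reps=len(arr),
        n_failed=n_failed,
        resampling_unit=resampling_unit,
        seed=seed,
        point_curve=point_curve,
        fit=full_fit,
    )


def candidate_phs_specs() -> list[ModelSpec]:
    """The four candidate innocuous-PHS models.

    Condition-factor model; log10 innocuous x noxious TCF interaction model;
    innocuous-TCF-only; noxious-TCF-only (the noxious covariate is the
    participant-level log10 mean noxious TCF).
    """
    return [
        ModelSpec(
            formula="phs ~ C(contrast_condition, Treatment(32))",
            name="condition",
        ),
        ModelSpec(
            formula="phs ~ innocuous_log10_tcf * noxious_log10_tcf",
            name="tcf_interaction",
        ),
        ModelSpec(formula="phs ~ innocuous_log10_tcf", name="innocuous_tcf"),
        ModelSpec(formula="phs ~ noxious_log10_tcf", name="noxious_tcf"),
    ]


def compare_models(
    specs: list[ModelSpec],
    data: pd.DataFrame,
    n_reps: int = 2000,
    resampling_unit: str = "row",
    seed: int | None = None,
    n_quad: int = 1,
) -> tuple[pd.DataFrame, dict[str, BootstrapAUCResult]]:
    """Rank candidate models by point AUC (ties broken by lower AIC, then
    input order).

    All specs must share the response column.  Returns the comparison table
    (one row per model, ranked) and the per-model bootstrap results.
    """
    responses = {s.response for s in specs}
    if len(responses) != 1:
        raise ValueError(f"candidate models have mismatched responses: {responses}")
    ss = np.random.SeedSequence(seed)
    subseeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(specs))]
    results: dict[str, BootstrapAUCResult] = {}
    rows = []
    for i, (spec, sub) in enumerate(zip(specs, subseeds)):
        res = bootstrap_model_auc(
            spec, data, n_reps=n_reps, resampling_unit=resampling_unit,
            seed=sub, n_quad=n_quad,
        )
        results[spec.label] = res
        rows.append(
            {
                "model": spec.label,
                "formula": spec.formula,
                "point_auc": res.point_auc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "aic": res.fit.aic,
                "n_failed_reps": res.n_failed,
                "order": i,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["point_auc", "aic", "order"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table = table.drop(columns="order")
    return table, results


def marginal_effects(
    fit: MixedModelFit,
    predictor: str,
    grid,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Predicted PHS probability over a grid of one predictor.

    Other continuous predictors are held at their sample means, categorical
    predictors at their reference level, and the random intercept at 0.
    Confidence bands are delta-method Wald intervals computed on the linear
    predictor and mapped through the logistic function.  Grid values outside
    the observed predictor range trigger a warning.
    """
    if fit.model_data is None or predictor not in fit.model_data.columns:
        raise ValueError(f"predictor {predictor!r} not part of the fitted model")
    grid = np.asarray(grid, dtype=float)
    observed = fit.model_data[predictor]
    if grid.min() < observed.min() - 1e-9 or grid.max() > observed.max() + 1e-9:
        warnings.warn(
            f"grid extends outside the observed range of {predictor} "
            f"[{observed.min():.3g}, {observed.max():.3g}]",
            stacklevel=2,
        )
    new = {}
    for col in fit.model_data.columns:
        if col == predictor:
            continue
        series = fit.model_data[col]
        if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
            new[col] = np.full(len(grid), float(series.mean()))
        else:
            new[col] = np.full(len(grid), series.iloc[0])
    new[predictor] = grid
    (X,) = patsy.build_design_matrices(
        [fit.design_info], pd.DataFrame(new), return_type="dataframe"
    )
    Xa = np.asarray(X)
    eta = Xa @ fit.params.to_numpy()
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", Xa, fit.cov_params.to_numpy(), Xa))
    zq = norm.ppf(0.5 + conf_level / 2)
    return pd.DataFrame(
        {
            predictor: grid,
            "eta": eta,
            "se_eta": se_eta,
            "prob": expit(eta),
            "ci_low": expit(eta - zq * se_eta),
            "ci_high": expit(eta + zq * se_eta),
        }
    )
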