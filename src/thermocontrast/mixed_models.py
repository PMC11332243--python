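"""Random-intercept mixed models for clustered psychophysics trials.

Trials are nested within participants, so every regression here carries a
participant random intercept ``(1|ID)``.  Two families are provided:

* **Logistic** (PHS outcomes): the marginal likelihood integrates the random
  intercept out of the Bernoulli likelihood per participant.  The integral
  is approximated by adaptive Gauss-Hermite quadrature centred and scaled at
  each participant's conditional mode; with one node this is exactly the
  Laplace approximation, which is the default.  Fixed effects and log(sigma_u)
  are optimised jointly by L-BFGS-B; Wald standard errors come from the
  numerical Hessian at the optimum, and odds ratios are the exponentiated
  log-odds coefficients with Wald 95% intervals.

* **Gaussian** (TSL threshold models): delegated to statsmodels' linear
  mixed model (REML by default, ML for likelihood-ratio testing), wrapped in
  the same result container.  t statistics use a residual degrees-of-freedom
  approximation (n_obs - n_fixed).

Also here: the likelihood-ratio omnibus test for interaction terms, Tukey-
adjusted pairwise contrasts of a fitted factor, the QST-covariate control
model, and the Monte-Carlo power calculation for a logistic effect.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, studentized_range, t as t_dist

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "ContrastResult",
    "PowerResult",
    "SeparationError",
    "fit_logistic_mixed",
    "fit_linear_mixed",
    "omnibus_interaction_test",
    "pairwise_contrasts",
    "qst_control_model",
    "power_simulation",
]

QST_COLUMNS = (
    "qst_cold_detection",
    "qst_warm_detection",
    "qst_cold_pain",
    "qst_heat_pain",
)


class SeparationError(RuntimeError):
    """Raised when a logistic fit is degenerate (constant response or
    complete separation)."""


@dataclass(frozen=True)
class ModelSpec:
    """A mixed-model specification.

    ``formula`` is a patsy formula for the response and fixed effects, e.g.
    ``"phs ~ C(contrast_condition, Treatment(32)) * task"``; the random
    intercept over ``groups`` is implicit.  ``family`` is ``"binomial"``
    (logit link) or ``"gaussian"``.
    """

    formula: str
    groups: str = "participant_id"
    family: str = "binomial"
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        if "~" not in self.formula:
            raise ValueError("formula must contain '~'")

    @property
    def response(self) -> str:
        return self.formula.split("~")[0].strip()

    @property
    def label(self) -> str:
        return self.name or f"{self.formula} + (1|{self.groups})"


@dataclass
class MixedModelFit:
    """Container for a fitted mixed model.

    ``params``/``se``/``z``/``p_values`` are indexed by design-matrix column
    name; ``odds_ratios`` (binomial only) holds OR with Wald 95% bounds;
    ``random_intercept_sd`` is the group-level SD; ``n_params`` counts fixed
    effects plus variance parameters, so ``aic == 2*n_params - 2*loglik``.
    """

    spec: ModelSpec
    params: pd.Series
    se: pd.Series
    z: pd.Series
    p_values: pd.Series
    cov_params: pd.DataFrame
    odds_ratios: pd.DataFrame | None
    random_intercept_sd: float
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool
    method: str
    design_info: object = field(repr=False, default=None)
    model_data: pd.DataFrame | None = field(repr=False, default=None)
    df_resid: float | None = None

    def to_dict(self) -> dict:
        out = {
            "model": self.spec.label,
            "formula": f"{self.spec.formula} + (1|{self.spec.groups})",
            "family": self.spec.family,
            "coefficients": {
                name: {
                    "estimate": float(self.params[name]),
                    "se": float(self.se[name]),
                    ("z" if self.spec.family == "binomial" else "t"): float(self.z[name]),
                    "p": float(self.p_values[name]),
                }
                for name in self.params.index
            },
            "random_intercept_sd": float(self.random_intercept_sd),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n_obs": int(self.n_obs),
            "n_groups": int(self.n_groups),
            "converged": bool(self.converged),
            "singular": bool(self.singular),
            "method": self.method,
        }
        if self.odds_ratios is not None:
            out["odds_ratios"] = {
                name: {
                    "or": float(r["or"]),
                    "ci_low": float(r["ci_low"]),
                    "ci_high": float(r["ci_high"]),
                }
                for name, r in self.odds_ratios.iterrows()
            }
        return out


@dataclass(frozen=True)
class ContrastResult:
    pair: str
    estimate: float
    se: float
    z_ratio: float
    p_value: float
    adjusted_p: float
    adjustment: str


@dataclass(frozen=True)
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    reps: int
    alpha: float
    odds_ratio: float
    predictor: str


# ---------------------------------------------------------------------------
# logistic mixed model (hand-authored marginal likelihood)
# ---------------------------------------------------------------------------


def _design(spec: ModelSpec, data: pd.DataFrame):
    data = data.reset_index(drop=True)  # resampled tables carry duplicate labels
    y_df, X_df = patsy.dmatrices(spec.formula, data, return_type="dataframe")
    y = np.asarray(y_df).ravel()
    X = np.asarray(X_df)
    if X.shape[1] > np.linalg.matrix_rank(X):
        raise ValueError("design matrix is rank deficient (collinear predictors)")
    groups_raw = data.loc[X_df.index, spec.groups]
    codes, uniques = pd.factorize(groups_raw, sort=True)
    return y, X, list(X_df.columns), codes, len(uniques), X_df, data

def _group_modes(eta0, y, g, n_groups, sigma2, u0, n_iter=50, tol=1e-11):
    """Newton iteration for the conditional modes of all random intercepts,
    vectorised over groups."""
    u = u0.copy()
    for _ in range(n_iter):
        eta = eta0 + u[g]
        mu = expit(eta)
        grad = np.bincount(g, weights=y - mu, minlength=n_groups) - u / sigma2
        hess = -np.bincount(g, weights=mu * (1 - mu), minlength=n_groups) - 1.0 / sigma2
        step = grad / hess
        u = u - step
        if np.max(np.abs(step)) < tol:
            break
    eta = eta0 + u[g]
    mu = expit(eta)
    curv = np.bincount(g, weights=mu * (1 - mu), minlength=n_groups) + 1.0 / sigma2
    return u, curv


def _cond_loglik_by_group(eta0, y, g, n_groups, u):
    eta = eta0 + u[g]
    # y*eta - log(1+e^eta), numerically stable
    ll = y * eta - np.logaddexp(0.0, eta)
    return np.bincount(g, weights=ll, minlength=n_groups)


def _marginal_nll(theta, y, X, g, n_groups, n_quad, mode_cache, sigma_fixed=None):
    p = X.shape[1]
    beta = theta[:p]
    sigma = sigma_fixed if sigma_fixed is not None else float(np.exp(theta[p]))
    eta0 = X @ beta
    if sigma < 1e-8:
        ll = y * eta0 - np.logaddexp(0.0, eta0)
        return -float(np.sum(ll))
    sigma2 = sigma**2
    u, curv = _group_modes(eta0, y, g, n_groups, sigma2, mode_cache["u"])
    mode_cache["u"] = u
    if n_quad == 1:  # Laplace
        f = _cond_loglik_by_group(eta0, y, g, n_groups, u) - u**2 / (2 * sigma2)
        ll_groups = f - 0.5 * np.log(curv) - np.log(sigma)
    else:  # adaptive Gauss-Hermite centred at the modes
        nodes, weights = hermgauss(n_quad)
        s = 1.0 / np.sqrt(curv)
        terms = np.empty((n_quad, n_groups))
        for k in range(n_quad):
            uk = u + np.sqrt(2.0) * s * nodes[k]
            f = _cond_loglik_by_group(eta0, y, g, n_groups, uk) - uk**2 / (2 * sigma2)
            terms[k] = np.log(weights[k]) + f + nodes[k] ** 2
        m = terms.max(axis=0)
        ll_groups = (
            m
            + np.log(np.sum(np.exp(terms - m), axis=0))
            + 0.5 * np.log(2.0)
            + np.log(s)
            - np.log(sigma)
            - 0.5 * np.log(2 * np.pi)
        )
    return -float(np.sum(ll_groups))


def _numerical_hessian(fun, x, step=1e-4):
    n = len(x)
    H = np.empty((n, n))
    h = step * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_logistic_mixed(
    spec: ModelSpec,
    data: pd.DataFrame,
    n_quad: int = 1,
    sigma_u: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixedModelFit:
    """Fit a random-intercept logistic regression by (adaptive) quadrature.

    Parameters
    ----------
    spec:
        Model specification (``family`` must be ``"binomial"``).
    data:
        Long-format trial table; the response column must be binary.
    n_quad:
        Gauss-Hermite nodes; 1 (default) is the Laplace approximation.
    sigma_u:
        If given, the random-intercept SD is held fixed at this value
        (``0`` reduces the model to ordinary logistic regression); otherwise
        it is estimated.

    Raises
    ------
    SeparationError
        For a constant response or apparent complete separation.
    ValueError
        For a rank-deficient design or fewer than two groups (when
        estimating ``sigma_u``).
    """
    if spec.family != "binomial":
        raise ValueError("fit_logistic_mixed requires a binomial spec")
    y, X, names, g, n_groups, X_df, data = _design(spec, data)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("response must be binary 0/1")
    if len(uniq) < 2:
        raise SeparationError("response is constant: model is degenerate")
    if sigma_u is None and n_groups < 2:
        raise ValueError("need at least 2 groups to estimate sigma_u")

    p = X.shape[1]
    beta0 = np.zeros(p)
    ybar = y.mean()
    if names[0].lower() in ("intercept",):
        beta0[0] = logit(min(max(ybar, 1e-4), 1 - 1e-4))
    mode_cache = {"u": np.zeros(n_groups)}

    estimate_sigma = sigma_u is None
    if estimate_sigma:
        x0 = np.concatenate([beta0, [0.0]])  # log sigma = 0
        bounds = [(None, None)] * p + [(-8.0, 5.0)]
        nll = lambda th: _marginal_nll(th, y, X, g, n_groups, n_quad, mode_cache)
    else:
        x0 = beta0
        bounds = [(None, None)] * p
        nll = lambda th: _marginal_nll(
            th, y, X, g, n_groups, n_quad, mode_cache, sigma_fixed=float(sigma_u)
        )

    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
    )
    theta = res.x
    beta = theta[:p]
    sigma = float(np.exp(theta[p])) if estimate_sigma else float(sigma_u)
    singular = estimate_sigma and theta[p] <= -7.5
    if singular:
        sigma = 0.0
    # complete separation: every observation fitted with near-certainty on
    # the correct side.  Large but finite coefficients with moderate margins
    # are legitimate on small-scale predictors and are not flagged.
    margins = (2 * y - 1) * (X @ beta)
    if np.min(margins) > 8:
        raise SeparationError(
            "response is completely separated: all outcomes fitted with "
            "near-certain probabilities"
        )

    # Wald covariance from the numerical Hessian; ill-conditioned optima can
    # defeat a single step size, so widen until the diagonal is positive
    cov_all = np.full((len(theta), len(theta)), np.nan)
    se_all = np.full(len(theta), np.nan)
    for step in (1e-4, 1e-3, 1e-2):
        H = _numerical_hessian(nll, theta, step=step)
        try:
            cov_try = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            continue
        d = np.diag(cov_try)[:p]
        if np.all(np.isfinite(d)) and np.all(d > 0):
            cov_all = cov_try
            se_all = np.sqrt(np.clip(np.diag(cov_try), 0, None))
            break

    params = pd.Series(beta, index=names)
    se = pd.Series(se_all[:p], index=names)
    z = params / se
    pvals = pd.Series(2 * norm.sf(np.abs(z)), index=names)
    ors = pd.DataFrame(
        {
            "or": np.exp(params),
            "ci_low": np.exp(params - 1.959963984540054 * se),
            "ci_high": np.exp(params + 1.959963984540054 * se),
        },
        index=names,
    )
    loglik = -res.fun
    n_params = p + (1 if estimate_sigma or (sigma_u or 0) > 0 else 0)
    method = "laplace" if n_quad == 1 else f"agh{n_quad}"
    if not estimate_sigma:
        method += f"(sigma_u={sigma_u:g} fixed)"
    return MixedModelFit(
        spec=spec,
        params=params,
        se=se,
        z=z,
        p_values=pvals,
        cov_params=pd.DataFrame(cov_all[:p, :p], index=names, columns=names),
        odds_ratios=ors,
        random_intercept_sd=sigma,
        loglik=float(loglik),
        aic=float(2 * n_params - 2 * loglik),
        n_params=n_params,
        n_obs=len(y),
        n_groups=n_groups,
        converged=bool(res.success),
        singular=bool(singular),
        method=method,
        design_info=X_df.design_info,
        model_data=data.loc[X_df.index].copy(),
    )


# ---------------------------------------------------------------------------
# linear mixed model (statsmodels backend)
# ---------------------------------------------------------------------------


def fit_linear_mixed(spec: ModelSpec, data: pd.DataFrame, reml: bool = True) -> MixedModelFit:
    """Fit a random-intercept linear model (REML by default).

    Wald t statistics use the residual degrees-of-freedom approximation
    ``n_obs - n_fixed``.  A near-zero random-intercept variance is reported
    via the ``singular`` flag, not raised.  Use ``reml=False`` (maximum
    likelihood) for fits entering likelihood-ratio tests.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_linear_mixed requires a gaussian spec")
    data = data.reset_index(drop=True)
    y_df, X_df = patsy.dmatrices(spec.formula, data, return_type="dataframe")
    names = list(X_df.columns)
    if X_df.shape[1] > np.linalg.matrix_rank(np.asarray(X_df)):
        raise ValueError("design matrix is rank deficient (collinear predictors)")
    groups = data.loc[X_df.index, spec.groups]
    model = sm.MixedLM(np.asarray(y_df).ravel(), np.asarray(X_df), groups=np.asarray(groups))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
    p = len(names)
    params = pd.Series(result.fe_params, index=names)
    se = pd.Series(np.asarray(result.bse_fe), index=names)
    tvals = params / se
    df_resid = float(len(y_df) - p)
    pvals = pd.Series(2 * t_dist.sf(np.abs(tvals), df_resid), index=names)
    var_re = float(np.asarray(result.cov_re).ravel()[0])
    n_params = p + 2  # random-intercept variance + residual variance
    loglik = float(result.llf)
    return MixedModelFit(
        spec=spec,
        params=params,
        se=se,
        z=tvals,
        p_values=pvals,
        cov_params=pd.DataFrame(
            np.asarray(result.cov_params())[:p, :p], index=names, columns=names
        ),
        odds_ratios=None,
        random_intercept_sd=float(np.sqrt(max(var_re, 0.0))),
        loglik=loglik,
        aic=float(2 * n_params - 2 * loglik),
        n_params=n_params,
        n_obs=int(len(y_df)),
        n_groups=int(groups.nunique()),
        converged=bool(result.converged),
        singular=bool(var_re < 1e-8),
        method="reml" if reml else "ml",
        design_info=X_df.design_info,
        model_data=data.loc[X_df.index].copy(),
    )


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------


def omnibus_interaction_test(full: MixedModelFit, reduced: MixedModelFit):
    """Likelihood-ratio test of nested mixed models.

    ``chi2 = 2 * (loglik_full - loglik_reduced)`` on ``df`` equal to the
    parameter-count difference.  Both fits must be on the same data and
    family and estimated by maximum likelihood (REML loglikelihoods are not
    comparable across fixed-effect structures).
    """
    if full.spec.family != reduced.spec.family:
        raise ValueError("models have different families")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fit to different data")
    if full.spec.family == "gaussian" and (full.method != "ml" or reduced.method != "ml"):
        raise ValueError("refit gaussian models with reml=False for the LRT")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    if df == 0:
        return 0.0, 0, 1.0
    if not set(reduced.params.index).issubset(full.params.index):
        raise ValueError("models do not appear to be nested")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return float(chi2), int(df), float(chi2_dist.sf(chi2, df))


_LEVEL_RE = re.compile(r"\[T\.(.+?)\]$")


def pairwise_contrasts(
    fit: MixedModelFit, factor: str, adjust: str = "tukey"
) -> list[ContrastResult]:
    """All pairwise contrasts of a treatment-coded factor's levels.

    Contrasts are differences on the linear-predictor scale, evaluated at
    the reference level of any interacting factors (interaction terms are
    not included in the contrast vectors).  ``adjust`` is ``"tukey"``
    (studentized-range, the default for a 3-level factor), ``"bonferroni"``
    or ``"none"``.
    """
    main_cols = [
        name
        for name in fit.params.index
        if factor in name and ":" not in name and _LEVEL_RE.search(name)
    ]
    if not main_cols:
        raise ValueError(f"factor {factor!r} not found among fitted terms")
    levels = {}
    for name in main_cols:
        levels[_LEVEL_RE.search(name).group(1)] = name
    ref_label = None
    if fit.model_data is not None and factor in fit.model_data.columns:
        observed = {str(v) for v in fit.model_data[factor].unique()}
        rest = observed - set(levels)
        if len(rest) == 1:
            ref_label = rest.pop()
    if ref_label is None:
        ref_label = "ref"
    all_levels = [ref_label] + list(levels)
    k = len(all_levels)
    V = fit.cov_params
    idx = list(fit.params.index)

    def coef_vector(level: str) -> np.ndarray:
        v = np.zeros(len(idx))
        if level in levels:
            v[idx.index(levels[level])] = 1.0
        return v

    out = []
    for la, lb in combinations(all_levels, 2):
        c = coef_vector(lb) - coef_vector(la)  # (later level - earlier level)
        est = float(c @ fit.params.to_numpy())
        se = float(np.sqrt(c @ V.to_numpy() @ c))
        zr = est / se
        p_raw = float(2 * norm.sf(abs(zr)))
        if adjust == "tukey":
            p_adj = float(studentized_range.sf(abs(zr) * np.sqrt(2.0), k, 1e6))
        elif adjust == "bonferroni":
            p_adj = min(1.0, p_raw * (k * (k - 1) // 2))
        elif adjust == "none":
            p_adj = p_raw
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        out.append(
            ContrastResult(
                pair=f"{lb} - {la}",
                estimate=est,
                se=se,
                z_ratio=zr,
                p_value=p_raw,
                adjusted_p=p_adj,
                adjustment=adjust,
            )
        )
    return out


def qst_control_model(
    participants: pd.DataFrame,
    model_table: pd.DataFrame,
    n_quad: int = 1,
) -> MixedModelFit:
    """Control model: innocuous PHS on QST detection and pain thresholds.

    Tests whether static thermal sensitivity (quantitative sensory testing
    thresholds, a participant-level covariate table) predicts PHS; reported
    alongside the thermal-contrast models for comparison.
    """
    missing = [c for c in QST_COLUMNS if c not in participants.columns]
    if missing:
        raise ValueError(f"participants table missing QST column(s): {missing}")
    cols = ["participant_id", *QST_COLUMNS]
    data = model_table.drop(columns=[c for c in QST_COLUMNS if c in model_table], errors="ignore")
    data = data.merge(participants[cols], on="participant_id", how="left")
    spec = ModelSpec(
        formula="phs ~ " + " + ".join(QST_COLUMNS),
        family="binomial",
        name="qst_control",
    )
    return fit_logistic_mixed(spec, data, n_quad=n_quad)


# ---------------------------------------------------------------------------
# power simulation
# ---------------------------------------------------------------------------


def _wald_p_logistic(x: np.ndarray, y: np.ndarray) -> float:
    """Wald p-value for the slope of a plain logistic regression (Newton)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(60):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return np.nan
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    if np.max(np.abs(beta)) > 30:
        return np.nan
    cov = np.linalg.inv(X.T @ (X * (expit(X @ beta) * (1 - expit(X @ beta)))[:, None]))
    z = beta[1] / np.sqrt(cov[1, 1])
    return float(2 * norm.sf(abs(z)))


def power_simulation(
    n_groups: int,
    trials_per_group: int,
    odds_ratio: float,
    predictor_distribution: str = "lognormal",
    *,
    baseline_rate: float,
    alpha: float = 0.05,
    reps: int = 500,
    sigma_u: float = 0.0,
    seed: int | None = None,
) -> PowerResult:
    """Monte-Carlo power of the two-tailed Wald test for a logistic effect.

    Simulates ``reps`` studies of ``n_groups * trials_per_group``
    observations with predictor ``x`` drawn standard lognormal or standard
    normal, outcome ``y ~ Bernoulli(logistic(logit(baseline_rate) +
    log(odds_ratio) * x + u))``, and counts Wald rejections of the slope at
    ``alpha``.  ``baseline_rate`` (the event probability at x = 0) must be
    supplied: power depends strongly on it.  Returns the rejection fraction
    with a normal-approximation 95% Monte-Carlo interval.
    """
    if predictor_distribution not in ("lognormal", "normal"):
        raise ValueError(f"unknown predictor distribution {predictor_distribution!r}")
    if reps < 100:
        raise ValueError("reps must be at least 100 for a usable power estimate")
    if not 0 < baseline_rate < 1:
        raise ValueError("baseline_rate must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = n_groups * trials_per_group
    b0 = logit(baseline_rate)
    b1 = np.log(odds_ratio)
    rejections = 0
    used = 0
    for _ in range(reps):
        if predictor_distribution == "lognormal":
            x = rng.lognormal(0.0, 1.0, n)
        else:
            x = rng.normal(0.0, 1.0, n)
        eta = b0 + b1 * x
        if sigma_u > 0:
            u = rng.normal(0.0, sigma_u, n_groups)
            eta = eta + np.repeat(u, trials_per_group)
        y = (rng.random(n) < expit(eta)).astype(float)
        if y.min() == y.max():
            continue
        p = _wald_p_logistic(x, y)
        if np.isnan(p):
            continue
        used += 1
        rejections += p < alpha
    if used == 0:
        raise RuntimeError("all replicates degenerate; adjust baseline_rate or n")
    power = rejections / used
    half = 1.959963984540054 * np.sqrt(max(power * (1 - power), 1e-12) / used)
    return PowerResult(
        power=float(power),
        ci_low=float(max(0.0, power - half)),
        ci_high=float(min(1.0, power + half)),
        reps=used,
        alpha=alpha,
        odds_ratio=odds_ratio,
        predictor=predictor_distribution,
    )
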