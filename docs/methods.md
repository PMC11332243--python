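# Methods

## The task being simulated

The adapted thermal sensory limen (TSL) protocol alternates warming and
cooling of a single skin site. A trial starts at the 32 °C baseline, ramps
at 1 °C/s to a fixed warm peak — 32, 38 or 44 °C, defining the low, medium
and high thermal-contrast conditions — then descends through baseline (an
auditory tone marks the start of the response window; when the peak equals
baseline the tone instead sounds after a 2 s hold) and continues into the
cold range until the participant presses a button, after which it returns
to the peak. Responses are only valid below 32 °C; 0 °C is the safety
floor. Each participant completes both task instructions — *innocuous*
(respond to any change in sensation) then *noxious* (respond to pain) — for
each condition in the fixed order 32 → 38 → 44 °C, with 3 practice plus 3
experimental trials per cell: 36 trials in all. Practice trials are
generated and flagged but never analysed.

A *paradoxical heat sensation* (PHS) is a "warm"/"heat pain" report in the
innocuous task or a "heat pain" report in the noxious task, given during
cooling. The trial's thermal contrast is
`TCF = (T_warm − T_cold) / 50` with cut-offs 50 and 0 °C, and the analyses
work with `log10(TCF)`.

## Generative model

Participants are drawn independently; each has

- per-condition mean trough temperatures for the two tasks, equal to
  population means plus a participant-level shift
  (`N(0, 1.0²)` innocuous, `N(0, 3.0²)` noxious, clipped so that
  0 < noxious < innocuous < 32 °C always holds);
- trial-to-trial trough noise (SD 1.2 °C innocuous, 3.0 °C noxious),
  troughs truncated to `[safety_floor, 31.9]` and quantised to 0.1 °C so
  that the 0.1 s-sampled, 1 °C/s trace hits them exactly;
- a random intercept `u_i ~ N(0, σ_u²)`, default σ_u = 1;
- age, gender and four QST thresholds (cold/warm detection, cold/heat
  pain) as participant covariates, drawn independently of `u_i` so the QST
  control model is a true null under the generator.

PHS on a trial is Bernoulli with log-odds
`β₀ + β₁·log10(TCF) + u_i` in the innocuous task and separate coefficients
`β₀ⁿ + β₁ⁿ·log10(TCF) + u_i` in the noxious task.

**Default coefficients.** β₁ = 2.6 is the natural log of the reported
innocuous-TCF odds ratio scale (e^2.6 ≈ 13.5 per tenfold contrast
increase). β₀ = −0.7 was then set, before any testing, so that the marginal
probability of at least one innocuous PHS across the three low-contrast
experimental trials is ≈ 8% of participants (≈ 17 of 208), using the
standard logit-normal marginalisation `logistic(η/√(1 + 0.346 σ_u²))`.
A consequence worth stating plainly: with the trial-level slope pinned at
2.6, the implied high-contrast prevalence (≈ 85/208) is steeper than the
between-condition differences reported for real cohorts (≈ 50/208). Real
data exhibit within-condition correlation between troughs and PHS propensity
that this generator deliberately omits; simulated between-condition effect
sizes (McNemar χ², Cohen's g) are therefore larger in magnitude than
observed ones, while trial-level quantities (the TCF odds ratio, model
ranking, AUC scale) are comparable. Passing tests validate the machinery
and the trial-level model, not the exact between-condition effect sizes of
any particular cohort.

The noxious defaults (β₀ⁿ = −4, β₁ⁿ = 0) encode the empirical finding that
noxious PHS is rare and shows no clear contrast dependence; trough means
(11.0/12.9/13.1 °C noxious, 29.5/29.0/28.5 °C innocuous) reproduce the
reported directions of threshold shifts across conditions (+1.9/+2.1 °C
noxious, −0.5/−1.0 °C innocuous). Trough distributions and their variances
are conventions, not estimates — no published values exist for them.

**Randomness.** One seed drives everything. Participant *i* uses the
counter-derived substream `SeedSequence(seed, spawn_key=(i,))` (parameters)
and its first spawn (trials), so any participant subset reproduces
independently of cohort size and identical seeds give byte-identical
tables.

## Processing and exclusions

Analysis tables keep experimental trials only. A trial is valid if its
trough lies in [0, 32) °C, its peak in [32, 50] °C, and its report is in
the four-word vocabulary; participants missing any valid experimental trial
are excluded wholesale (complete-case rule) and counted. TCF ≤ 0 rows would
be dropped with a warning before the log transform (they cannot occur for
valid trials). TSL thresholds are z-scored within task over all retained
trials. The participant-level noxious contrast covariate is the mean of the
nine noxious experimental TCFs, log10-transformed after averaging
(mean-then-log; the alternative log-then-mean ordering is not used).

## Estimation

**Logistic mixed models** (PHS outcomes) are fit by maximising the marginal
likelihood of a single random intercept. The per-participant integral uses
adaptive Gauss–Hermite quadrature centred at the conditional mode with
curvature-based scaling; one node (the default) is exactly the Laplace
approximation, matching the common default of formula-based GLMM software,
and node counts up to 25 are available. Conditional modes are found by a
vectorised Newton iteration (tolerance 1e-11); fixed effects and log σ_u
are optimised jointly by L-BFGS-B (relative tolerance 1e-8, ≤ 500
iterations, log σ_u bounded in [−8, 5]; hitting the lower bound is reported
as a singular fit with σ_u = 0). Wald standard errors come from the inverse
numerical Hessian at the optimum (central differences; the step widens
10-fold, up to twice, if the inverse is not positive on the diagonal —
flat bootstrap optima can defeat a single step size). Odds ratios are
exponentiated coefficients with Wald 95% intervals. AIC is
`2k − 2·loglik` with k counting fixed effects plus the intercept variance.
A constant response raises immediately; complete separation is diagnosed
when every observation is fitted with near-certain probability on its own
side (classification margins all > 8 on the logit scale) — a
coefficient-magnitude cut is deliberately not used, because rare-event
resamples produce legitimately large coefficients on small-scale
log10-TCF predictors. The σ_u = 0 limit is available as a fixed-variance
fit and reproduces ordinary IRLS logistic regression; the Laplace fit is
cross-checked against R's lme4 in the test suite.

**Linear mixed models** (threshold outcomes) delegate to statsmodels'
MixedLM (REML by default; ML for fits entering likelihood-ratio tests).
t statistics use the residual degrees-of-freedom approximation
`n_obs − n_fixed`; a Satterthwaite engine is out of scope, so p-values for
small designs are mildly anti-conservative relative to Satterthwaite.

**Omnibus interaction tests** are likelihood-ratio χ² between nested ML
fits with df equal to the parameter difference. **Pairwise contrasts** of a
treatment-coded factor are formed from the main-effect coefficients (i.e.
at the reference level of interacting factors), with Tukey adjustment via
the studentized-range distribution (df → ∞); Bonferroni and unadjusted
variants are available. **McNemar tests** use the continuity-corrected
closed form `(|b−c|−1)²/(b+c)` by default (both variants exposed and
recorded); Cohen's `g = b/(b+c) − ½` with the lower-contrast condition
first, so PHS increasing with contrast gives negative g. Note the corrected
statistic exceeds the uncorrected one in the degenerate tie case b = c
(0.1 vs 0 at b = c = 5); monotonicity of the correction holds whenever
|b − c| ≥ 1.

**Power** for a logistic effect is estimated by Monte-Carlo simulation of
plain logistic fits (Newton/IRLS) with a standard lognormal or standard
normal predictor. The baseline event rate is a required argument, not a
hidden default, because power depends on it strongly and no canonical value
exists.

## Model comparison

Four candidate innocuous-PHS models are compared: condition factor,
innocuous×noxious log10-TCF interaction, innocuous TCF only, noxious TCF
only. Discrimination is the trapezoidal AUC of the ROC curve (ties step
diagonally; equivalent to the tie-corrected Mann–Whitney estimator, against
which it is verified exhaustively in tests). Per bootstrap replicate, a
training and a test set are drawn *independently with replacement, each of
the original size* (not the out-of-bag convention); the model is refit on
training and scored on test using fixed effects only, since test resamples
may contain participants unseen in training. The 95% interval is the
2.5/97.5 percentile over replicates (not BCa); failed replicates are
dropped and counted, and more than 10% failures aborts. Resampling is by
row by default, with a participant-level mode (keeping each participant's
trials together) offered because trials are clustered; the unit is recorded
in the output. The winner is the highest point AUC, ties broken by lower
AIC, then input order. Marginal-effect curves hold other continuous
predictors at their sample means and the random intercept at 0, with
delta-method intervals mapped through the logistic function; they are
intended for continuous predictors.

## Problem sizes

Defaults follow the study design (208 participants, 2000 bootstrap
replicates). The packaged verification scripts use scaled sizes chosen as
reasonable Monte-Carlo designs: 200 replicate cohorts for parameter
recovery, 50 replicate cohorts of n = 300 with point-AUC ranking for
model-comparison recovery, 2000 null tables (n = 208) for McNemar
calibration, 500 null simulations of a 60-participant design for omnibus
LRT calibration, and a 200-replicate bootstrap in the acceptance run.

## Known limitations

- No reaction-time or skin-biophysics modelling; troughs are truncated
  normals, so threshold distributions have no heavy left tail.
- No within-participant correlation between trough depth and PHS propensity
  (see the prevalence-slope consequence above).
- Random intercepts only: no random slopes, crossed effects or Bayesian
  estimation.
- Pairwise contrasts are reference-level, not marginalised over
  interacting factors.
- The deposited-study ingestion path is exercised with synthetic
  schema-conformant CSVs; analyses of real exports inherit all of the
  modelling caveats above.
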