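# thermocontrast

Trial-level simulation and statistical modelling of **paradoxical heat
sensation** (PHS) — the illusory feeling of warmth or heat pain while the
skin is cooling — in the **thermal sensory limen** (TSL) task.

The package is aimed at thermal psychophysicists and biostatisticians who
want a fully testable, download-free implementation of the contrast-based
analysis of PHS: a generative simulator of a contrast-controlled TSL study,
the Thermal Contrast Function, paired prevalence tests, participant-level
random-intercept mixed models, and bootstrapped ROC/AUC model comparison.
External trial tables in the same CSV schema (e.g. real study exports) run
through the identical pipeline.

## The model

Each TSL trial ramps a thermode from a 32 °C baseline to a fixed warm peak
`T_warm ∈ {32, 38, 44} °C` (the low/medium/high contrast conditions), back
down through baseline at 1 °C/s into the cold range, until the participant
presses a button at the trough temperature `T_cold` (their TSL threshold).
The trial's **Thermal Contrast Function** normalises the warm→cold swing by
the admissible stimulator range:

```
TCF = (T_warm − T_cold) / (T_max warm − T_min cold),   T_max warm = 50 °C, T_min cold = 0 °C
```

so `TCF ∈ [0, 1]` is comparable across conditions, studies and populations.
PHS (a "warm"/"heat pain" report during cooling) is modelled at the trial
level by a participant-clustered logistic regression,

```
PHS_ij ~ Bernoulli( logistic( β₀ + β₁ · log10(TCF_ij) + u_i ) ),   u_i ~ N(0, σ_u²)
```

estimated by maximising the marginal likelihood with the random intercept
integrated out (Laplace approximation by default, adaptive Gauss–Hermite
quadrature optionally). Condition-pair prevalence differences use McNemar's
χ² with Cohen's *g*; threshold models use random-intercept linear
regression; candidate PHS models are compared by AIC and by AUC of ROC
curves with a paired train/test bootstrap.

## Worked example

```python
from thermocontrast import (
    GenerativeConfig, ModelSpec, simulate_dataset, prepare_analysis_table,
    innocuous_model_table, mcnemar_all_pairs, prevalence_summary, fit_logistic_mixed,
)

cfg = GenerativeConfig(n_participants=208, seed=1)        # the study design
ds = simulate_dataset(cfg)                                # 208 × 36 trials
analysis, summary, excl = prepare_analysis_table(ds.trials, ds.participants)

print(prevalence_summary(analysis).query("task == 'innocuous'")
      [["contrast_condition", "prevalence", "rate"]].to_string(index=False))

mcn = mcnemar_all_pairs(analysis).query(
    "task == 'innocuous' and pair == '32 vs 44'").iloc[0]
print(f"McNemar 32 vs 44: chi2(1) = {mcn.chi2:.2f}, p = {mcn.p_value:.2g}, "
      f"g = {mcn.cohens_g:.2f}")

table = innocuous_model_table(analysis, summary)
fit = fit_logistic_mixed(ModelSpec(formula="phs ~ innocuous_log10_tcf"), table)
orr = fit.odds_ratios.loc["innocuous_log10_tcf"]
print(f"log10-TCF slope = {fit.params['innocuous_log10_tcf']:.2f}, "
      f"OR = {orr['or']:.2f} (95% CI {orr['ci_low']:.2f}-{orr['ci_high']:.2f}), "
      f"sigma_u = {fit.random_intercept_sd:.2f}")
```

prints

```
 contrast_condition  prevalence  rate
                 32          15    15
                 38          53    61
                 44          84   102
McNemar 32 vs 44: chi2(1) = 57.09, p = 4.2e-14, g = -0.43
log10-TCF slope = 2.66, OR = 14.31 (95% CI 7.01-29.22), sigma_u = 0.72
```

Reading this: the number of participants with at least one innocuous PHS
(prevalence) rises steeply with the contrast condition; the paired McNemar
test confirms the 32 °C vs 44 °C difference (negative *g*: discordant
participants overwhelmingly show PHS only in the high-contrast condition);
and each tenfold increase in thermal contrast multiplies the odds of a PHS
trial by ≈ 14, with participant heterogeneity σ_u ≈ 0.7 log-odds units.

The same analysis runs end to end from a shell:

```sh
thermocontrast all --seed 1 --n-participants 208 --n-reps 2000 --out runs/demo
thermocontrast validate runs/demo/trials.csv
```

which writes `analysis.csv`, `mcnemar_results.csv`, `model_results.json`,
`comparison.csv`, `report.md` and a `manifest.json` with content hashes.

## Layout

- `src/thermocontrast/synthetic_tsl.py` — generative simulator (cohort, traces, trials)
- `src/thermocontrast/trial_processing.py` — TCF, PHS classification, analysis tables
- `src/thermocontrast/paired_prevalence.py` — McNemar / Cohen's g / prevalence
- `src/thermocontrast/mixed_models.py` — logistic & linear random-intercept models, LRT, contrasts, power
- `src/thermocontrast/model_comparison.py` — ROC/AUC, bootstrap, marginal effects
- `src/thermocontrast/pipeline.py`, `cli.py` — orchestration, validation, CLI

See `docs/methods.md` for the modelling assumptions and numerical choices.
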