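"""End-to-end orchestration: simulate -> process -> analyse -> compare -> report.

Each stage reads and writes plain CSV/JSON files in a run directory; a
``manifest.json`` records the configuration, the seed and a SHA-256 hash of
every output so a run can be verified and re-executed.  All randomness flows
from the run seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .mixed_models import (
    ModelSpec,
    fit_linear_mixed,
    fit_logistic_mixed,
    omnibus_interaction_test,
    pairwise_contrasts,
    qst_control_model,
)
from .model_comparison import (
    bootstrap_model_auc,
    candidate_phs_specs,
    compare_models,
    marginal_effects,
)
from .paired_prevalence import mcnemar_all_pairs, prevalence_summary
from .synthetic_tsl import GenerativeConfig, simulate_dataset, write_dataset
from .trial_processing import (
    REPORTS,
    TASKS,
    innocuous_model_table,
    prepare_analysis_table,
)

__all__ = ["RunConfig", "SchemaError", "run_pipeline", "validate_trials"]

logger = logging.getLogger("thermocontrast")

_TRIALS_SCHEMA = {
    "participant_id": object,
    "task": object,
    "contrast_condition": np.integer,
    "trial_index": np.integer,
    "is_practice": np.bool_,
    "t_warm_c": np.floating,
    "t_cold_c": np.floating,
    "report": object,
    "phs": np.bool_,
}


class SchemaError(ValueError):
    """An input table does not conform to the trials.csv schema."""


class RunConfig(BaseModel):
    """Configuration of one pipeline run.

    Exactly one input source: a generative configuration for a synthetic
    cohort, or a path to an external ``trials.csv`` (deposited study data
    mapped to the package schema).
    """

    generative: GenerativeConfig | None = None
    trials_csv: str | None = None
    participants_csv: str | None = None
    out_dir: str
    seed: int = 0
    n_reps: int = Field(default=2000, ge=0)
    resampling_unit: str = "row"
    save_traces: bool = False
    make_plots: bool = True
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if (self.generative is None) == (self.trials_csv is None):
            raise ValueError("exactly one of 'generative' or 'trials_csv' is required")
        if self.resampling_unit not in ("row", "participant"):
            raise ValueError("resampling_unit must be 'row' or 'participant'")
        return self


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_trials(path: str | Path) -> dict:
    """Validate an external trial table against the schema and protocol rules.

    Returns a report of per-rule violation counts; missing required columns
    raise :class:`SchemaError` naming the column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in _TRIALS_SCHEMA if c not in df.columns]
    if missing:
        raise SchemaError(f"trials table missing required column(s): {', '.join(missing)}")
    rules = {
        "task in vocabulary": ~df["task"].isin(TASKS),
        "report in vocabulary": ~df["report"].isin(REPORTS),
        "trough below baseline": ~(df["t_cold_c"] < 32.0),
        "trough at or above 0 degC": ~(df["t_cold_c"] >= 0.0),
        "peak within [32, 50] degC": ~df["t_warm_c"].between(32.0, 50.0),
        "trough below peak": ~(df["t_cold_c"] < df["t_warm_c"]),
    }
    report = {
        "path": str(path),
        "n_rows": int(len(df)),
        "violations": {rule: int(mask.sum()) for rule, mask in rules.items()},
    }
    report["n_invalid_rows"] = int(np.column_stack(list(rules.values())).any(axis=1).sum())
    return report


def _load_trials(path: str | Path) -> pd.DataFrame:
    report = validate_trials(path)
    df = pd.read_csv(path)
    logger.info("loaded %d trial rows (%d invalid)", report["n_rows"], report["n_invalid_rows"])
    return df


def _fit_payload(fit, extras: dict | None = None) -> dict:
    out = fit.to_dict()
    if extras:
        out.update(extras)
    return out


def _study_models(analysis, summary, participants, seed) -> dict:
    """Fit the full inference stack and return a JSON-ready payload."""
    results: dict = {}

    both = analysis.copy()
    both["phs"] = both["phs"].astype(int)
    spec_1a = ModelSpec(
        formula="phs ~ C(contrast_condition, Treatment(32)) * C(task, Treatment('innocuous'))",
        name="phs_condition_by_task",
    )
    spec_1a_red = ModelSpec(
        formula="phs ~ C(contrast_condition, Treatment(32)) + C(task, Treatment('innocuous'))",
        name="phs_condition_plus_task",
    )
    fit_1a = fit_logistic_mixed(spec_1a, both)
    fit_1a_red = fit_logistic_mixed(spec_1a_red, both)
    chi2, df, p = omnibus_interaction_test(fit_1a, fit_1a_red)
    contrasts = pairwise_contrasts(fit_1a, "contrast_condition")
    results["phs_condition_by_task"] = _fit_payload(
        fit_1a,
        {
            "omnibus_interaction": {"chi2": chi2, "df": df, "p": p},
            "pairwise_contrasts_condition": [c.__dict__ for c in contrasts],
        },
    )
    logger.info("omnibus interaction: chi2(%d) = %.2f, p = %.3g", df, chi2, p)

    for task, name in (("innocuous", "innocuous_tsl"), ("noxious", "noxious_tsl")):
        sub = analysis.loc[analysis["task"] == task]
        spec = ModelSpec(
            formula="t_cold_c ~ C(contrast_condition, Treatment(32)) + trial_index",
            family="gaussian",
            name=f"{name}_by_condition",
        )
        results[f"{name}_by_condition"] = _fit_payload(fit_linear_mixed(spec, sub))

    table = innocuous_model_table(analysis, summary, participants)
    spec_2c = ModelSpec(
        formula="phs ~ innocuous_tsl_z * noxious_tsl_z", name="phs_tsl_thresholds"
    )
    results["phs_tsl_thresholds"] = _fit_payload(fit_logistic_mixed(spec_2c, table))

    for spec in candidate_phs_specs()[1:]:  # the three TCF models
        results[f"phs_{spec.name}"] = _fit_payload(fit_logistic_mixed(spec, table))

    if participants is not None and "qst_cold_detection" in participants.columns:
        results["qst_control"] = _fit_payload(qst_control_model(participants, table))

    return results


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the run directory.

    Outputs: ``participants.csv``/``trials.csv`` (synthetic runs),
    ``analysis.csv``, ``participants_summary.csv``, ``exclusions.json``,
    ``prevalence.csv``, ``mcnemar_results.csv``, ``model_results.json``,
    ``comparison.csv``, ``roc_points.csv``, ``marginal_effects.csv``,
    ``report.md`` and ``manifest.json`` (with content hashes).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # -- simulate or load -------------------------------------------------
    participants = None
    if config.generative is not None:
        gcfg = config.generative.model_copy(update={"seed": config.seed})
        logger.info("simulating %d participants (seed %d)", gcfg.n_participants, gcfg.seed)
        ds = simulate_dataset(gcfg, include_traces=config.save_traces)
        paths = write_dataset(ds, out, save_traces=config.save_traces)
        written += [paths["participants"], paths["trials"]]
        trials = ds.trials
        participants = ds.participants
    else:
        trials = _load_trials(config.trials_csv)
        if config.participants_csv:
            participants = pd.read_csv(config.participants_csv)

    # -- process ----------------------------------------------------------
    analysis, summary, exclusions = prepare_analysis_table(trials, participants)
    logger.info(
        "analysis set: %d trials, %d participants excluded",
        len(analysis),
        exclusions["n_participants_excluded"],
    )
    analysis.to_csv(out / "analysis.csv", index=False)
    summary.to_csv(out / "participants_summary.csv", index=False)
    (out / "exclusions.json").write_text(json.dumps(exclusions, indent=1))
    written += [out / "analysis.csv", out / "participants_summary.csv", out / "exclusions.json"]

    # -- paired prevalence ------------------------------------------------
    prev = prevalence_summary(analysis)
    mcn = mcnemar_all_pairs(analysis)
    prev.to_csv(out / "prevalence.csv", index=False)
    mcn.to_csv(out / "mcnemar_results.csv", index=False)
    written += [out / "prevalence.csv", out / "mcnemar_results.csv"]

    # -- mixed models -----------------------------------------------------
    model_results = _study_models(analysis, summary, participants, config.seed)
    (out / "model_results.json").write_text(json.dumps(model_results, indent=1))
    written.append(out / "model_results.json")

    # -- model comparison -------------------------------------------------
    table = innocuous_model_table(analysis, summary, participants)
    comparison, boot = compare_models(
        candidate_phs_specs(),
        table,
        n_reps=config.n_reps,
        resampling_unit=config.resampling_unit,
        seed=config.seed,
    )
    comparison.to_csv(out / "comparison.csv", index=False)
    written.append(out / "comparison.csv")

    roc_rows = []
    for label, res in boot.items():
        for f, t, thr in zip(res.point_curve.fpr, res.point_curve.tpr, res.point_curve.thresholds):
            roc_rows.append({"model": label, "fpr": f, "tpr": t, "threshold": thr})
    pd.DataFrame(roc_rows).to_csv(out / "roc_points.csv", index=False)
    written.append(out / "roc_points.csv")

    winner_label = comparison.iloc[0]["model"]
    winner = boot[winner_label]
    me_rows = []
    for predictor in ("innocuous_log10_tcf", "noxious_log10_tcf"):
        if predictor in winner.fit.model_data.columns and predictor in winner.fit.spec.formula:
            x = winner.fit.model_data[predictor]
            grid = np.linspace(x.min(), x.max(), 50)
            me = marginal_effects(winner.fit, predictor, grid)
            me.insert(0, "predictor", predictor)
            me = me.rename(columns={predictor: "value"})
            me_rows.append(me)
    if me_rows:
        pd.concat(me_rows).to_csv(out / "marginal_effects.csv", index=False)
        written.append(out / "marginal_effects.csv")

    if config.make_plots:
        try:
            _plot_roc(boot, out / "roc.png")
            written.append(out / "roc.png")
        except Exception as exc:  # plotting is best-effort
            logger.warning("ROC plot failed: %s", exc)

    # -- report + manifest ------------------------------------------------
    report = _render_report(config, exclusions, prev, mcn, model_results, comparison)
    (out / "report.md").write_text(report)
    written.append(out / "report.md")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "files": {p.name: _sha256(p) for p in written if p.is_file()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "out_dir": str(out),
        "manifest": manifest,
        "comparison": comparison,
        "mcnemar": mcn,
        "prevalence": prev,
        "model_results": model_results,
        "exclusions": exclusions,
    }


def _plot_roc(boot, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, res in boot.items():
        ax.plot(res.point_curve.fpr, res.point_curve.tpr, label=f"{label} (AUC {res.point_auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _render_report(config, exclusions, prev, mcn, model_results, comparison) -> str:
    lines = [
        "# Thermal contrast analysis report",
        "",
        f"Seed: {config.seed}; bootstrap replicates: {config.n_reps} "
        f"({config.resampling_unit} resampling).",
        "",
        f"Participants excluded (incomplete trials): "
        f"{exclusions['n_participants_excluded']} of {exclusions['n_participants_in']}.",
        "",
        "## PHS prevalence and rate",
        "",
        prev.to_markdown(index=False),
        "",
        "## McNemar condition-pair tests (Cohen's g)",
        "",
        mcn[["task", "pair", "chi2", "p_value", "cohens_g"]].to_markdown(index=False),
        "",
        "## Mixed models",
        "",
    ]
    for name, payload in model_results.items():
        lines.append(f"### {name}")
        lines.append("")
        lines.append(f"`{payload['formula']}` — AIC {payload['aic']:.1f}, "
                     f"sigma_u {payload['random_intercept_sd']:.2f}")
        if "omnibus_interaction" in payload:
            o = payload["omnibus_interaction"]
            lines.append(
                f"Omnibus interaction LRT: chi2({o['df']}) = {o['chi2']:.2f}, p = {o['p']:.3g}"
            )
        for cname, c in payload["coefficients"].items():
            stat = c.get("z", c.get("t"))
            lines.append(f"- {cname}: {c['estimate']:.3f} (SE {c['se']:.3f}, p = {c['p']:.3g})")
        lines.append("")
    lines += [
        "## Model comparison (bootstrapped AUC)",
        "",
        comparison.to_markdown(index=False),
        "",
        f"Winning model: **{comparison.iloc[0]['model']}**",
        "",
    ]
    return "\n".join(lines)
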