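"""Trial-level processing for the adapted thermal sensory limen (TSL) task.

A TSL trial alternates skin warming and cooling with a single thermode.  The
peak (``t_warm``) is the fixed starting temperature of the contrast condition
(32, 38 or 44 degC) and the trough (``t_cold``) is the probe temperature at the
moment the participant presses the button during the cooling phase.  This
module turns raw temperature traces or long-format trial tables into
analysis-ready records: peak/trough extraction, paradoxical heat sensation
(PHS) classification, the Thermal Contrast Function, log transforms,
z-scoring of thresholds and exclusion of incomplete participants.

The Thermal Contrast Function (TCF) normalises the warm-to-cold swing of one
trial by the full admissible temperature range of the stimulator::

    TCF = (t_warm - t_cold) / (t_max_warm - t_min_cold)

with default cut-offs of 50 degC (maximum safe warm temperature) and 0 degC
(minimum safe cold temperature), so TCF lies in [0, 1] and is comparable
across conditions, experiments and populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .synthetic_tsl import TemperatureTrace

__all__ = [
    "BASELINE_C",
    "REPORTS",
    "TASKS",
    "InvalidTrialError",
    "TCFParams",
    "DEFAULT_TCF_PARAMS",
    "compute_tcf",
    "classify_phs",
    "extract_trial",
    "prepare_analysis_table",
    "innocuous_model_table",
]

#: Baseline (neutral) probe temperature in degC; the cooling phase and the
#: response window begin once the probe drops below this value.
BASELINE_C: float = 32.0

TASKS: tuple[str, ...] = ("innocuous", "noxious")
REPORTS: tuple[str, ...] = ("cold", "warm", "cold pain", "heat pain")

#: Reports that constitute a paradoxical heat sensation, per task.  In the
#: innocuous task any warm/heat percept during cooling is paradoxical; in the
#: noxious task only heat pain is.
_PHS_REPORTS: dict[str, frozenset[str]] = {
    "innocuous": frozenset({"warm", "heat pain"}),
    "noxious": frozenset({"heat pain"}),
}

_REQUIRED_TRIAL_COLUMNS = (
    "participant_id",
    "task",
    "contrast_condition",
    "trial_index",
    "is_practice",
    "t_warm_c",
    "t_cold_c",
    "report",
    "phs",
)


class InvalidTrialError(ValueError):
    """Raised when a trace or trial violates the task protocol."""


@dataclass(frozen=True)
class TCFParams:
    """Temperature cut-offs of the Thermal Contrast Function.

    Parameters
    ----------
    t_max_warm:
        Maximum possible probe temperature in degC (default 50).
    t_min_cold:
        Minimum possible probe temperature in degC (default 0).
    """

    t_max_warm: float = 50.0
    t_min_cold: float = 0.0

    def __post_init__(self) -> None:
        if not self.t_max_warm > self.t_min_cold:
            raise ValueError(
                f"t_max_warm ({self.t_max_warm}) must exceed t_min_cold "
                f"({self.t_min_cold})"
            )


DEFAULT_TCF_PARAMS = TCFParams()


def compute_tcf(t_warm, t_cold, params: TCFParams = DEFAULT_TCF_PARAMS):
    """Thermal Contrast Function of one or more trials.

    ``(t_warm - t_cold) / (t_max_warm - t_min_cold)``, the warm-to-cold
    temperature swing normalised by the admissible range; unitless in [0, 1].

    Parameters
    ----------
    t_warm, t_cold:
        Peak and trough temperature of the trial in degC.  Scalars or
        array-likes of equal shape.
    params:
        Temperature cut-offs; defaults to 50 / 0 degC.

    Returns
    -------
    float or ndarray
        TCF value(s).  ``t_warm == t_cold`` is allowed as a degenerate input
        and returns 0.

    Raises
    ------
    ValueError
        If any ``t_cold > t_warm`` or any temperature lies outside
        ``[t_min_cold, t_max_warm]``.
    """
    tw = np.asarray(t_warm, dtype=float)
    tc = np.asarray(t_cold, dtype=float)
    if np.any(tc > tw):
        raise ValueError("t_cold must not exceed t_warm")
    if np.any(tw > params.t_max_warm) or np.any(tc < params.t_min_cold):
        raise ValueError(
            f"temperatures outside [{params.t_min_cold}, {params.t_max_warm}] degC"
        )
    out = (tw - tc) / (params.t_max_warm - params.t_min_cold)
    if out.ndim == 0:
        return float(out)
    return out


def classify_phs(task: str, report: str) -> bool:
    """Classify a verbal report as paradoxical heat sensation (PHS).

    PHS is the perception of warmth or heat (innocuous task) or of heat pain
    (noxious task) while the skin is cooling.
    """
    if task not in _PHS_REPORTS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if report not in REPORTS:
        raise ValueError(f"unknown report {report!r}; expected one of {REPORTS}")
    return report in _PHS_REPORTS[task]


def extract_trial(trace: "TemperatureTrace") -> dict:
    """Extract a trial record from a temperature trace.

    The peak is the maximum probe temperature of the trace (the configured
    starting temperature of the condition) and the TSL threshold is the probe
    temperature at the button press, obtained by linear interpolation on the
    trace.  Responses are only valid in the cooling phase, i.e. after the
    tone and strictly below baseline.

    Returns a dict with the trial-table schema columns plus a
    ``missing_response`` flag; ``t_cold_c`` is NaN when no press occurred.

    Raises
    ------
    InvalidTrialError
        If the press precedes the tone or the press temperature is not below
        baseline (32 degC).
    """
    times = np.asarray(trace.samples, dtype=float)[:, 0]
    temps = np.asarray(trace.samples, dtype=float)[:, 1]
    meta = trace.trial_meta
    t_warm = float(np.max(temps))
    record = {
        "participant_id": meta["participant_id"],
        "task": meta["task"],
        "contrast_condition": meta["contrast_condition"],
        "trial_index": meta["trial_index"],
        "is_practice": meta.get("is_practice", False),
        "t_warm_c": t_warm,
        "t_cold_c": np.nan,
        "report": meta.get("report"),
        "phs": None,
        "missing_response": True,
    }
    if trace.press_time is None:
        return record
    if trace.press_time < trace.tone_time:
        raise InvalidTrialError(
            f"button press at {trace.press_time:.2f}s precedes tone at "
            f"{trace.tone_time:.2f}s"
        )
    t_cold = float(np.interp(trace.press_time, times, temps))
    if t_cold >= BASELINE_C:
        raise InvalidTrialError(
            f"press at {t_cold:.1f} degC is not below the {BASELINE_C:.0f} degC "
            "baseline: responses are only permitted in the cooling range"
        )
    record["t_cold_c"] = t_cold
    record["missing_response"] = False
    if record["report"] is not None:
        record["phs"] = classify_phs(meta["task"], record["report"])
    return record


def _validity_mask(trials: pd.DataFrame, params: TCFParams) -> pd.Series:
    """Per-row protocol validity of experimental trials."""
    ok = trials["t_cold_c"].notna()
    ok &= trials["t_cold_c"] < BASELINE_C
    ok &= trials["t_cold_c"] >= params.t_min_cold
    ok &= trials["t_warm_c"] >= BASELINE_C
    ok &= trials["t_warm_c"] <= params.t_max_warm
    ok &= trials["report"].isin(REPORTS)
    ok &= trials["task"].isin(TASKS)
    return ok


def prepare_analysis_table(
    trials: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    params: TCFParams = DEFAULT_TCF_PARAMS,
    n_experimental: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Build the analysis table and per-participant summary.

    Practice trials are dropped; participants with any missing or invalid
    experimental trial are excluded wholesale (mirroring the study's
    complete-case rule); per-trial TCF and log10(TCF) are computed; TSL
    thresholds are z-scored within task over all retained trials; and the
    per-participant mean noxious TCF is computed and log10-transformed.

    Parameters
    ----------
    trials:
        Long-format trial table with the ``trials.csv`` schema.
    participants:
        Optional participant covariate table (age, gender, QST thresholds),
        merged into the summary when given.
    n_experimental:
        Experimental trials expected per (task, condition) cell.

    Returns
    -------
    (analysis, summary, exclusions)
        ``analysis``: retained experimental trials with ``tcf``,
        ``log10_tcf`` and ``tsl_z`` columns.  ``summary``: one row per
        retained participant with mean noxious TCF (and its log10), and
        per-condition innocuous/noxious PHS presence and rates.
        ``exclusions``: counts and identities of excluded participants and
        dropped rows.

    Raises
    ------
    ValueError
        If the analysis set is empty or a threshold column has zero variance
        under z-scoring.
    """
    missing = [c for c in _REQUIRED_TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing column(s): {', '.join(missing)}")

    conditions = sorted(trials["contrast_condition"].unique())
    expected = n_experimental * len(conditions) * len(TASKS)

    exp = trials.loc[~trials["is_practice"].astype(bool)].copy()
    valid = _validity_mask(exp, params)
    n_invalid_rows = int((~valid).sum())

    # complete-case rule: a participant must contribute every experimental
    # trial of every cell, all valid
    counts = exp.loc[valid].groupby("participant_id").size()
    complete = counts[counts >= expected].index
    all_ids = pd.Index(trials["participant_id"].unique())
    excluded_ids = sorted(all_ids.difference(complete))

    analysis = exp.loc[valid & exp["participant_id"].isin(complete)].copy()
    if analysis.empty:
        raise ValueError("analysis set is empty after exclusions")

    analysis["phs"] = [
        classify_phs(t, r) for t, r in zip(analysis["task"], analysis["report"])
    ]
    analysis["tcf"] = compute_tcf(
        analysis["t_warm_c"].to_numpy(), analysis["t_cold_c"].to_numpy(), params
    )
    nonpos = analysis["tcf"] <= 0
    if nonpos.any():
        warnings.warn(
            f"dropping {int(nonpos.sum())} trial(s) with TCF <= 0 before log10",
            stacklevel=2,
        )
        analysis = analysis.loc[~nonpos].copy()
    analysis["log10_tcf"] = np.log10(analysis["tcf"])

    # z-score TSL thresholds within task over the retained trials
    analysis["tsl_z"] = np.nan
    for task in TASKS:
        m = analysis["task"] == task
        if not m.any():
            continue
        x = analysis.loc[m, "t_cold_c"]
        sd = x.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"zero variance in {task} TSL thresholds: cannot z-score")
        analysis.loc[m, "tsl_z"] = (x - x.mean()) / sd

    summary = _participant_summary(analysis, conditions)
    if participants is not None:
        summary = summary.merge(participants, on="participant_id", how="left")

    exclusions = {
        "n_participants_in": int(len(all_ids)),
        "n_participants_excluded": len(excluded_ids),
        "excluded_participant_ids": [str(i) for i in excluded_ids],
        "n_invalid_rows": n_invalid_rows,
        "n_tcf_nonpositive_rows": int(nonpos.sum()),
        "n_trials_retained": int(len(analysis)),
    }
    return analysis.reset_index(drop=True), summary, exclusions


def _participant_summary(analysis: pd.DataFrame, conditions) -> pd.DataFrame:
    nox = analysis.loc[analysis["task"] == "noxious"]
    inn = analysis.loc[analysis["task"] == "innocuous"]
    out = (
        nox.groupby("participant_id")["tcf"]
        .mean()
        .rename("mean_noxious_tcf")
        .to_frame()
    )
    out["log10_mean_noxious_tcf"] = np.log10(out["mean_noxious_tcf"])
    for cond in conditions:
        for task, sub in (("innocuous", inn), ("noxious", nox)):
            cell = sub.loc[sub["contrast_condition"] == cond]
            g = cell.groupby("participant_id")["phs"]
            out[f"any_{task}_phs_{cond}"] = g.any().reindex(out.index).fillna(False)
            out[f"{task}_phs_rate_{cond}"] = (
                g.sum().reindex(out.index).fillna(0).astype(int)
            )
    return out.reset_index()


def innocuous_model_table(
    analysis: pd.DataFrame,
    summary: pd.DataFrame,
    participants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Innocuous-trial table for the PHS regression models.

    One row per innocuous experimental trial with:

    - ``phs`` (0/1 response), ``contrast_condition``, ``trial_index``;
    - ``innocuous_log10_tcf``: per-trial log10 TCF;
    - ``noxious_log10_tcf``: the participant's log10 *mean* noxious TCF
      (a participant-level covariate, constant across their rows);
    - ``innocuous_tsl_z``: the trial's z-scored threshold;
    - ``noxious_tsl_z``: the z-scored threshold of the matching noxious trial
      (same participant, condition and trial index);
    - participant covariates (age, gender, QST thresholds) when supplied.
    """
    inn = analysis.loc[analysis["task"] == "innocuous"].copy()
    inn = inn.rename(
        columns={"log10_tcf": "innocuous_log10_tcf", "tsl_z": "innocuous_tsl_z"}
    )
    nox = analysis.loc[analysis["task"] == "noxious", :][
        ["participant_id", "contrast_condition", "trial_index", "tsl_z"]
    ].rename(columns={"tsl_z": "noxious_tsl_z"})
    table = inn.merge(
        nox, on=["participant_id", "contrast_condition", "trial_index"], how="left"
    )
    table = table.merge(
        summary[["participant_id", "log10_mean_noxious_tcf"]],
        on="participant_id",
        how="left",
    ).rename(columns={"log10_mean_noxious_tcf": "noxious_log10_tcf"})
    if participants is not None:
        table = table.merge(participants, on="participant_id", how="left")
    table["phs"] = table["phs"].astype(int)
    return table
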