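"""Generative simulator for the adapted thermal sensory limen (TSL) protocol.

Emulates a cohort of healthy participants performing the contrast-controlled
TSL task: each trial ramps the thermode from a 32 degC baseline up to a fixed
warm peak (32, 38 or 44 degC — the low/medium/high contrast conditions), back
down through baseline (where a tone opens the response window), and into the
cold range at 1 degC/s until the participant presses a button; the probe then
returns to the peak.  Participants complete 36 trials: 2 tasks (innocuous
change detection, then noxious pain detection) x 3 conditions x (3 practice +
3 experimental) trials, in a fixed order for everyone.

The generative model for paradoxical heat sensation (PHS) is a
participant-clustered logistic regression on the log10 thermal contrast of
the trial::

    phs ~ Bernoulli( logistic( beta0 + beta1 * log10(TCF) + u_i ) )

with participant random intercepts ``u_i ~ Normal(0, sigma_u^2)``.  Button
press (trough) temperatures are drawn from participant- and condition-
specific normals truncated to the permitted cold range, standing in for the
reaction-time dynamics of real participants.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit

from .trial_processing import BASELINE_C, classify_phs, compute_tcf

__all__ = [
    "CONDITIONS",
    "TASKS",
    "GenerativeConfig",
    "ParticipantParams",
    "TemperatureTrace",
    "SimulatedDataset",
    "generate_participants",
    "simulate_trial",
    "simulate_phs",
    "simulate_dataset",
    "write_dataset",
]

TASKS: tuple[str, str] = ("innocuous", "noxious")
CONDITIONS: tuple[int, int, int] = (32, 38, 44)

# Temperatures are stored at 0.1 degC resolution: with a 1 degC/s ramp and a
# 0.1 s sampling interval the probe moves in 0.1 degC steps, so troughs
# quantised to 0.1 degC are hit exactly by the trace.
_RES = 0.1


class GenerativeConfig(BaseModel):
    """All knobs of the synthetic TSL study.

    Defaults reproduce the study design: 208 participants, peaks
    {32, 38, 44} degC, 1 degC/s ramps, a 2 s baseline hold (tone at 2 s) when
    the peak equals baseline, 3 practice + 3 experimental trials per cell
    (36 trials per participant), and a safety floor of 0 degC.

    ``beta0``/``beta1`` are the innocuous-task PHS coefficients (log-odds
    intercept and slope per unit log10 TCF); ``beta0_noxious``/
    ``beta1_noxious`` the noxious-task ones (no contrast dependence by
    default); ``sigma_u`` the SD of participant random intercepts.
    """

    n_participants: int = Field(default=208, ge=1)
    peak_temperatures: tuple[int, ...] = (32, 38, 44)
    baseline: float = 32.0
    ramp_rate: float = Field(default=1.0, gt=0)
    baseline_hold: float = Field(default=2.0, ge=0)
    n_practice: int = Field(default=3, ge=0)
    n_experimental: int = Field(default=3, ge=1)
    safety_floor: float = Field(default=0.0, ge=0)
    sample_interval: float = Field(default=0.1, gt=0)

    # PHS generative model (log-odds scale)
    beta0: float = -0.7
    beta1: float = 2.6
    beta0_noxious: float = -4.0
    beta1_noxious: float = 0.0
    sigma_u: float = Field(default=1.0, ge=0)

    # population trough structure (degC): means per condition, between- and
    # within-participant SDs
    innocuous_trough_mean: dict[int, float] = Field(
        default_factory=lambda: {32: 29.5, 38: 29.0, 44: 28.5}
    )
    noxious_trough_mean: dict[int, float] = Field(
        default_factory=lambda: {32: 11.0, 38: 12.9, 44: 13.1}
    )
    between_sd_innocuous: float = Field(default=1.0, ge=0)
    between_sd_noxious: float = Field(default=3.0, ge=0)
    trough_sd_innocuous: float = Field(default=1.2, gt=0)
    trough_sd_noxious: float = Field(default=3.0, gt=0)

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GenerativeConfig":
        if any(p > 50 for p in self.peak_temperatures):
            raise ValueError("peak temperatures must not exceed 50 degC")
        if any(p < self.baseline for p in self.peak_temperatures):
            raise ValueError("peaks must be at or above baseline")
        for cond in self.peak_temperatures:
            if cond not in self.innocuous_trough_mean or cond not in self.noxious_trough_mean:
                raise ValueError(f"trough means missing for condition {cond}")
            nox = self.noxious_trough_mean[cond]
            inn = self.innocuous_trough_mean[cond]
            if not (0 < nox < inn < self.baseline):
                raise ValueError(
                    f"condition {cond}: need 0 < noxious ({nox}) < innocuous "
                    f"({inn}) < {self.baseline}"
                )
        return self

    def trials_per_participant(self) -> int:
        per_cell = self.n_practice + self.n_experimental
        return per_cell * len(self.peak_temperatures) * len(TASKS)


@dataclass
class ParticipantParams:
    """Latent generative parameters of one simulated participant.

    ``innocuous_trough_mean`` / ``noxious_trough_mean`` map each contrast
    condition to the participant's mean button-press temperature (degC);
    ``random_intercept`` is the participant's deviation u_i in PHS log-odds;
    the ``qst_*`` fields emulate the quantitative-sensory-testing covariate
    table (thermal detection and pain thresholds in degC).
    """

    participant_id: str
    age: float
    gender: str
    innocuous_trough_mean: dict[int, float]
    noxious_trough_mean: dict[int, float]
    trough_sd_innocuous: float
    trough_sd_noxious: float
    random_intercept: float
    qst_cold_detection: float
    qst_warm_detection: float
    qst_cold_pain: float
    qst_heat_pain: float

    def __post_init__(self) -> None:
        for cond, inn in self.innocuous_trough_mean.items():
            nox = self.noxious_trough_mean[cond]
            if not (0 < nox < inn < BASELINE_C):
                raise ValueError(
                    f"{self.participant_id}, condition {cond}: trough means must "
                    f"satisfy 0 < noxious ({nox:.2f}) < innocuous ({inn:.2f}) < 32"
                )
        if not (self.trough_sd_innocuous > 0 and self.trough_sd_noxious > 0):
            raise ValueError("trough SDs must be positive")
        for name in ("qst_cold_detection", "qst_warm_detection", "qst_cold_pain", "qst_heat_pain"):
            v = getattr(self, name)
            if not (0 <= v <= 50):
                raise ValueError(f"{name} = {v} outside [0, 50] degC")


@dataclass
class TemperatureTrace:
    """Time-stamped probe temperature of one trial.

    ``samples`` is an (N, 2) array of (time s, temperature degC) at a fixed
    sampling interval; ``tone_time`` marks the downward baseline crossing
    (or the end of the baseline hold when peak == baseline); ``press_time``
    is the button press, or None for a missing response.  ``trial_meta``
    carries participant/task/condition/trial bookkeeping plus the verbal
    report.
    """

    samples: np.ndarray
    tone_time: float
    press_time: float | None
    trial_meta: dict


@dataclass
class SimulatedDataset:
    """Output bundle of :func:`simulate_dataset`."""

    trials: pd.DataFrame
    participants: pd.DataFrame
    participant_params: list[ParticipantParams]
    traces: list[TemperatureTrace] | None = None
    config: GenerativeConfig | None = None


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    # counter-derived substream: participant subsets reproduce independently
    # of cohort size
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def generate_participants(config: GenerativeConfig) -> list[ParticipantParams]:
    """Draw the synthetic cohort.

    Deterministic given ``config.seed``: each participant uses a
    counter-derived RNG substream.  Random intercepts are centred normal with
    SD ``sigma_u``; per-condition trough means are population means plus a
    participant-level shift, clipped so that
    0 < noxious < innocuous < baseline always holds.
    """
    out: list[ParticipantParams] = []
    width = max(3, len(str(config.n_participants)))
    for i in range(config.n_participants):
        rng = _participant_rng(config.seed, i)
        age = float(np.clip(rng.normal(24.97, 5.19), 18, 49))
        gender = "woman" if rng.random() < 121 / 208 else "man"
        shift_inn = rng.normal(0.0, config.between_sd_innocuous)
        shift_nox = rng.normal(0.0, config.between_sd_noxious)
        inn = {
            c: float(np.clip(m + shift_inn, 26.0, 31.5))
            for c, m in config.innocuous_trough_mean.items()
        }
        nox = {
            c: float(np.clip(config.noxious_trough_mean[c] + shift_nox, 0.5, inn[c] - 2.0))
            for c in config.noxious_trough_mean
        }
        u = float(rng.normal(0.0, config.sigma_u)) if config.sigma_u > 0 else 0.0
        out.append(
            ParticipantParams(
                participant_id=f"P{i + 1:0{width}d}",
                age=age,
                gender=gender,
                innocuous_trough_mean=inn,
                noxious_trough_mean=nox,
                trough_sd_innocuous=config.trough_sd_innocuous,
                trough_sd_noxious=config.trough_sd_noxious,
                random_intercept=u,
                qst_cold_detection=float(np.clip(rng.normal(30.8, 0.8), 0, 50)),
                qst_warm_detection=float(np.clip(rng.normal(33.8, 1.0), 0, 50)),
                qst_cold_pain=float(np.clip(rng.normal(12.0, 8.0), 0, 32)),
                qst_heat_pain=float(np.clip(rng.normal(44.5, 2.5), 32, 50)),
            )
        )
    return out


def participants_frame(participants: list[ParticipantParams]) -> pd.DataFrame:
    """Flatten participant parameters into the ``participants.csv`` schema."""
    rows = []
    for p in participants:
        row = {
            "participant_id": p.participant_id,
            "age": p.age,
            "gender": p.gender,
            "random_intercept": p.random_intercept,
            "trough_sd_innocuous": p.trough_sd_innocuous,
            "trough_sd_noxious": p.trough_sd_noxious,
            "qst_cold_detection": p.qst_cold_detection,
            "qst_warm_detection": p.qst_warm_detection,
            "qst_cold_pain": p.qst_cold_pain,
            "qst_heat_pain": p.qst_heat_pain,
        }
        for c, v in p.innocuous_trough_mean.items():
            row[f"innocuous_trough_mean_{c}"] = v
        for c, v in p.noxious_trough_mean.items():
            row[f"noxious_trough_mean_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _sample_trough(
    participant: ParticipantParams,
    task: str,
    contrast_condition: int,
    config: GenerativeConfig,
    rng: np.random.Generator,
) -> float:
    """Button-press temperature: truncated normal, quantised to 0.1 degC."""
    if task == "innocuous":
        mean = participant.innocuous_trough_mean[contrast_condition]
        sd = participant.trough_sd_innocuous
    elif task == "noxious":
        mean = participant.noxious_trough_mean[contrast_condition]
        sd = participant.trough_sd_noxious
    else:
        raise ValueError(f"unknown task {task!r}")
    trough = rng.normal(mean, sd)
    hi = config.baseline - _RES  # strictly below baseline
    trough = float(np.clip(trough, config.safety_floor, hi))
    return round(round(trough / _RES) * _RES, 1)


def simulate_phs(
    participant: ParticipantParams,
    tcf: float,
    task: str,
    config: GenerativeConfig,
    rng: np.random.Generator,
) -> tuple[bool, str]:
    """Draw the PHS outcome and verbal report for one trial.

    ``phs ~ Bernoulli(logistic(beta0 + beta1 * log10(tcf) + u_i))`` with
    task-specific coefficients.  The report is the paradoxical percept
    ("warm" / "heat pain") when PHS occurs, the veridical cold percept
    ("cold" / "cold pain") otherwise.
    """
    if not 0 < tcf <= 1:
        raise ValueError(f"tcf must lie in (0, 1]; got {tcf}")
    if task == "innocuous":
        eta = config.beta0 + config.beta1 * np.log10(tcf)
    elif task == "noxious":
        eta = config.beta0_noxious + config.beta1_noxious * np.log10(tcf)
    else:
        raise ValueError(f"unknown task {task!r}")
    eta += participant.random_intercept
    phs = bool(rng.random() < expit(eta))
    if task == "innocuous":
        report = "warm" if phs else "cold"
    else:
        report = "heat pain" if phs else "cold pain"
    return phs, report


def _build_trace(
    peak: float,
    trough: float,
    config: GenerativeConfig,
    meta: dict,
) -> TemperatureTrace:
    """Piecewise-linear trace through baseline -> peak -> trough -> peak."""
    base = config.baseline
    rate = config.ramp_rate
    knots_t = [0.0]
    knots_T = [base]
    if peak > base:
        t_up = (peak - base) / rate
        knots_t.append(knots_t[-1] + t_up)
        knots_T.append(peak)
        tone_time = knots_t[-1] + (peak - base) / rate
    else:
        knots_t.append(config.baseline_hold)
        knots_T.append(base)
        tone_time = config.baseline_hold
    t_down = (knots_T[-1] - trough) / rate
    knots_t.append(knots_t[-1] + t_down)
    knots_T.append(trough)
    press_time = knots_t[-1]
    knots_t.append(knots_t[-1] + (peak - trough) / rate)
    knots_T.append(peak)
    n = int(round(knots_t[-1] / config.sample_interval)) + 1
    times = np.arange(n) * config.sample_interval
    temps = np.interp(times, knots_t, knots_T)
    samples = np.column_stack([times, np.round(temps, 1)])
    return TemperatureTrace(
        samples=samples,
        tone_time=round(tone_time, 10),
        press_time=round(press_time, 10),
        trial_meta=meta,
    )


def simulate_trial(
    participant: ParticipantParams,
    task: str,
    contrast_condition: int,
    trial_index: int,
    rng: np.random.Generator,
    config: GenerativeConfig,
    is_practice: bool = False,
) -> TemperatureTrace:
    """Simulate one full trial and return its temperature trace.

    Samples the trough, draws the PHS outcome from the logistic model, and
    builds the piecewise-linear trace with tone and press events.  The verbal
    report is stored in ``trial_meta``.
    """
    if contrast_condition not in config.peak_temperatures:
        raise ValueError(
            f"condition {contrast_condition} not in {config.peak_temperatures}"
        )
    trough = _sample_trough(participant, task, contrast_condition, config, rng)
    tcf = compute_tcf(float(contrast_condition), trough)
    phs, report = simulate_phs(participant, tcf, task, config, rng)
    meta = {
        "participant_id": participant.participant_id,
        "task": task,
        "contrast_condition": contrast_condition,
        "trial_index": trial_index,
        "is_practice": is_practice,
        "report": report,
        "phs": phs,
    }
    return _build_trace(float(contrast_condition), trough, config, meta)


def simulate_dataset(
    config: GenerativeConfig, include_traces: bool = False
) -> SimulatedDataset:
    """Simulate the whole study.

    Fixed block order for every participant — innocuous task before noxious,
    conditions 32 -> 38 -> 44 within task, practice trials before
    experimental within each cell — yielding 36 trials per participant under
    defaults.  Deterministic given ``config.seed``.

    With ``include_traces=False`` (the default) only the trial table is
    built, skipping the per-sample trace arrays; troughs, reports and trial
    order are identical either way because the same RNG draws are used.
    """
    participants = generate_participants(config)
    rows: list[dict] = []
    traces: list[TemperatureTrace] | None = [] if include_traces else None
    for i, p in enumerate(participants):
        rng = _participant_rng(config.seed, i).spawn(1)[0]
        for task in TASKS:
            for cond in config.peak_temperatures:
                for is_practice, n_trials in (
                    (True, config.n_practice),
                    (False, config.n_experimental),
                ):
                    for j in range(1, n_trials + 1):
                        trough = _sample_trough(p, task, cond, config, rng)
                        tcf = compute_tcf(float(cond), trough)
                        phs, report = simulate_phs(p, tcf, task, config, rng)
                        rows.append(
                            {
                                "participant_id": p.participant_id,
                                "task": task,
                                "contrast_condition": cond,
                                "trial_index": j,
                                "is_practice": is_practice,
                                "t_warm_c": float(cond),
                                "t_cold_c": trough,
                                "report": report,
                                "phs": phs,
                            }
                        )
                        if include_traces:
                            meta = dict(rows[-1])
                            meta.pop("t_warm_c"), meta.pop("t_cold_c")
                            traces.append(_build_trace(float(cond), trough, config, meta))
    trials = pd.DataFrame(rows)
    return SimulatedDataset(
        trials=trials,
        participants=participants_frame(participants),
        participant_params=participants,
        traces=traces,
        config=config,
    )


def write_dataset(
    dataset: SimulatedDataset, out_dir: str | Path, save_traces: bool = False
) -> dict[str, Path]:
    """Write ``participants.csv``, ``trials.csv`` and (optionally) traces.

    Traces go under ``traces/`` as one CSV (time_s, temp_c) per trial plus an
    ``events.json`` with tone and press times.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": out / "participants.csv",
        "trials": out / "trials.csv",
    }
    dataset.participants.to_csv(paths["participants"], index=False)
    dataset.trials.to_csv(paths["trials"], index=False)
    if save_traces and dataset.traces:
        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        events = {}
        for k, tr in enumerate(dataset.traces):
            m = tr.trial_meta
            stem = (
                f"{m['participant_id']}_{m['task']}_{m['contrast_condition']}"
                f"_{'p' if m['is_practice'] else 'e'}{m['trial_index']}"
            )
            pd.DataFrame(tr.samples, columns=["time_s", "temp_c"]).to_csv(
                tdir / f"{stem}.csv", index=False
            )
            events[stem] = {"tone_time_s": tr.tone_time, "press_time_s": tr.press_time}
        with open(tdir / "events.json", "w") as fh:
            json.dump(events, fh, indent=1)
        paths["traces"] = tdir
    return paths
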