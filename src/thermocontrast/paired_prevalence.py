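"""Paired prevalence analysis of PHS across contrast conditions.

A participant "has PHS" in a condition iff any of their experimental trials
in that condition is paradoxical.  Condition pairs are compared with
McNemar's chi-square test on the discordant counts, with Cohen's g as the
effect size: g = b/(b+c) - 1/2, where b counts participants with PHS only in
the first-listed (lower-contrast) condition.  PHS increasing with contrast
therefore yields negative g.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "PairedBinaryTable",
    "McNemarResult",
    "paired_table",
    "mcnemar_test",
    "phs_by_participant",
    "mcnemar_all_pairs",
    "prevalence_summary",
]


@dataclass(frozen=True)
class PairedBinaryTable:
    """2x2 paired table: a = PHS in both conditions, b = first only,
    c = second only, d = neither."""

    a: int
    b: int
    c: int
    d: int
    labels: tuple[str, str] = ("first", "second")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class McNemarResult:
    chi2: float
    df: int
    p_value: float
    cohens_g: float
    continuity_corrected: bool
    table: PairedBinaryTable


def paired_table(first, second, labels: tuple[str, str] = ("first", "second")) -> PairedBinaryTable:
    """Cross-tabulate per-participant PHS presence in two conditions.

    ``first`` and ``second`` are boolean Series indexed by participant (or
    equal-length arrays); the participant sets must match.
    """
    f = pd.Series(first).astype(bool)
    s = pd.Series(second).astype(bool)
    if len(f) == 0:
        raise ValueError("empty participant set")
    if not f.index.equals(s.index):
        if set(f.index) != set(s.index):
            raise ValueError("participant sets differ between conditions")
        s = s.reindex(f.index)
    return PairedBinaryTable(
        a=int((f & s).sum()),
        b=int((f & ~s).sum()),
        c=int((~f & s).sum()),
        d=int((~f & ~s).sum()),
        labels=labels,
    )


def mcnemar_test(table: PairedBinaryTable, continuity: bool = True) -> McNemarResult:
    """McNemar's chi-square test for paired binary outcomes.

    ``chi2 = (|b - c| - 1)^2 / (b + c)`` with the continuity correction
    (default), ``(b - c)^2 / (b + c)`` without; p from the upper tail of
    chi-square(1).  Cohen's g = b/(b+c) - 1/2.

    Raises
    ------
    ValueError
        If there are no discordant pairs (b + c = 0), for which the
        statistic is undefined.
    """
    b, c = table.b, table.c
    if b + c == 0:
        raise ValueError("no discordant pairs: McNemar statistic undefined")
    diff = abs(b - c) - 1 if continuity else b - c
    chi2 = float(diff**2 / (b + c))
    return McNemarResult(
        chi2=chi2,
        df=1,
        p_value=float(_chi2_dist.sf(chi2, 1)),
        cohens_g=float(b / (b + c) - 0.5),
        continuity_corrected=continuity,
        table=table,
    )


def phs_by_participant(analysis: pd.DataFrame, task: str) -> pd.DataFrame:
    """Per-participant any-trial PHS presence, participants x conditions."""
    sub = analysis.loc[analysis["task"] == task]
    return (
        sub.groupby(["participant_id", "contrast_condition"])["phs"]
        .any()
        .unstack("contrast_condition")
        .fillna(False)
    )


def mcnemar_all_pairs(analysis: pd.DataFrame, continuity: bool = True) -> pd.DataFrame:
    """All condition-pair McNemar tests, per task (six tests under the
    default three conditions)."""
    rows = []
    for task in analysis["task"].unique():
        wide = phs_by_participant(analysis, task)
        for lo, hi in combinations(sorted(wide.columns), 2):
            labels = (str(lo), str(hi))
            res = mcnemar_test(paired_table(wide[lo], wide[hi], labels), continuity)
            rows.append(
                {
                    "task": task,
                    "pair": f"{lo} vs {hi}",
                    "a": res.table.a,
                    "b": res.table.b,
                    "c": res.table.c,
                    "d": res.table.d,
                    "chi2": res.chi2,
                    "df": res.df,
                    "p_value": res.p_value,
                    "cohens_g": res.cohens_g,
                    "continuity_corrected": res.continuity_corrected,
                }
            )
    return pd.DataFrame(rows)


def prevalence_summary(analysis: pd.DataFrame) -> pd.DataFrame:
    """PHS prevalence and rate per task x condition.

    Prevalence is the number of participants with at least one PHS trial in
    the cell; rate is the total number of PHS trials (up to 3 per participant
    under the default design).
    """
    rows = []
    n_participants = analysis["participant_id"].nunique()
    for (task, cond), cell in analysis.groupby(["task", "contrast_condition"]):
        per = cell.groupby("participant_id")["phs"]
        rows.append(
            {
                "task": task,
                "contrast_condition": cond,
                "n_participants": n_participants,
                "prevalence": int(per.any().sum()),
                "rate": int(cell["phs"].sum()),
            }
        )
    return pd.DataFrame(rows)
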