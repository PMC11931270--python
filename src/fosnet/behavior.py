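"""Discrimination-index statistics for the novelty-preference task.

The discrimination index D2 = (tOO - tRO) / (tOO + tRO) contrasts time
spent exploring the object in the older spatial location (tOO) against the
more recent one (tRO).  Rats preferentially explore the older location
when they remember the order, so positive D2 indicates spatiotemporal
memory.  D2 is tested against the chance level of 0 with a one-sample
t-test per condition and between conditions with Welch's two-sample
t-test; Shapiro-Wilk normality is computed and reported alongside, and a
Wilcoxon signed-rank alternative to the one-sample test is available via a
flag for non-normal samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tables import BehaviorTable

__all__ = [
    "TestResult",
    "discrimination_index",
    "test_against_chance",
    "compare_conditions_d2",
    "shapiro_normality",
    "UndefinedIndexError",
    "DegenerateTestError",
]


class UndefinedIndexError(ValueError):
    """Both exploration times are zero: D2 is undefined and the subject
    should be flagged for exclusion."""


class DegenerateTestError(ValueError):
    """The requested test is degenerate (e.g. zero variance)."""


@dataclass(frozen=True)
class TestResult:
    """Statistic, degrees of freedom, two-sided p and effect size.

    ``effect_size`` is Cohen's d: mean/sd for the one-sample test against
    chance, difference of means over the pooled sd for the two-sample
    comparison.  ``df`` is None for tests without a df (Wilcoxon) and may
    be fractional for Welch's t.
    """

    statistic: float
    df: float | None
    p_value: float
    effect_size: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "n": self.n,
        }


def discrimination_index(t_old: float, t_recent: float) -> float:
    """D2 = (t_old - t_recent) / (t_old + t_recent).

    Antisymmetric in its arguments and invariant to rescaling both times;
    raises UndefinedIndexError when both times are zero.
    """
    if t_old < 0 or t_recent < 0:
        raise ValueError("exploration times must be >= 0")
    total = t_old + t_recent
    if total == 0:
        raise UndefinedIndexError(
            "no exploration of either object: D2 undefined")
    return (t_old - t_recent) / total


def test_against_chance(d2_values) -> TestResult:
    """One-sample t-test of D2 against the no-preference level 0.

    Returns t = mean/(sd/sqrt(n)) with df = n-1, two-sided p, and Cohen's
    d = mean/sd.
    """
    d2 = np.asarray(d2_values, dtype=float)
    if d2.size < 2:
        raise DegenerateTestError("need at least 2 subjects")
    sd = d2.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("all D2 values identical: zero variance")
    res = stats.ttest_1samp(d2, popmean=0.0)
    return TestResult(
        statistic=float(res.statistic),
        df=float(d2.size - 1),
        p_value=float(res.pvalue),
        effect_size=float(d2.mean() / sd),
        n=int(d2.size),
    )


def wilcoxon_against_chance(d2_values) -> TestResult:
    """Wilcoxon signed-rank alternative to ``test_against_chance``."""
    d2 = np.asarray(d2_values, dtype=float)
    if d2.size < 2:
        raise DegenerateTestError("need at least 2 subjects")
    if np.all(d2 == 0):
        raise DegenerateTestError("all D2 values are zero")
    res = stats.wilcoxon(d2, alternative="two-sided")
    sd = d2.std(ddof=1)
    effect = float(d2.mean() / sd) if sd > 0 else float("nan")
    return TestResult(
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        effect_size=effect,
        n=int(d2.size),
    )


def compare_conditions_d2(d2_a, d2_b, equal_var: bool = False) -> TestResult:
    """Two-sample t-test (Welch by default) between two conditions' D2.

    Unequal group sizes are accepted.  Cohen's d uses the pooled sd.
    """
    a = np.asarray(d2_a, dtype=float)
    b = np.asarray(d2_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateTestError("need at least 2 subjects per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # identical constants: no evidence of difference
            return TestResult(statistic=0.0, df=float(a.size + b.size - 2),
                              p_value=1.0, effect_size=0.0,
                              n=int(a.size + b.size))
        raise DegenerateTestError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    pooled_sd = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb)
                        / (a.size + b.size - 2))
    effect = float((a.mean() - b.mean()) / pooled_sd) if pooled_sd > 0 else 0.0
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        effect_size=effect,
        n=int(a.size + b.size),
    )


def shapiro_normality(values) -> dict:
    """Shapiro-Wilk W and p, reported alongside the t-tests."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3 or np.ptp(arr) == 0:
        return {"W": float("nan"), "p_value": float("nan"), "n": int(arr.size)}
    res = stats.shapiro(arr)
    return {"W": float(res.statistic), "p_value": float(res.pvalue),
            "n": int(arr.size)}


def condition_summary(table: BehaviorTable,
                      use_wilcoxon: bool = False) -> dict:
    """Per-condition behavioral report: D2 vector, totals, normality,
    and the test against chance."""
    d2 = table.d2
    total = (table.data["t_old"] + table.data["t_recent"]).to_numpy(float)
    test = (wilcoxon_against_chance(d2) if use_wilcoxon
            else test_against_chance(d2))
    return {
        "condition": table.condition,
        "n": int(d2.size),
        "d2": [float(v) for v in d2],
        "d2_mean": float(d2.mean()),
        "d2_sd": float(d2.std(ddof=1)),
        "total_exploration_s": [float(v) for v in total],
        "shapiro": shapiro_normality(d2),
        "test_vs_chance": test.to_dict(),
        "test_family": "wilcoxon" if use_wilcoxon else "t",
    }
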