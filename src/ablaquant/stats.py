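"""Cohort statistics: tumor-growth percent change, group tests, correlation.

Includes the ablation-consistency arithmetic connecting a predicted
fractional ablation to the expected treated-arm volume change: if the
control arm grows by c percent over an interval and a fraction f of the
treated tumor is ablated at its start, the expected treated change is
``100 ((1 + c/100)(1 - f) - 1)`` — e.g. a 135% control increase with
f = 0.2332 predicts ~80.2%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (InvalidBaselineError, InvalidFractionError,
                     TransformError, UndefinedCorrelationError)

__all__ = [
    "GrowthRecord",
    "GroupComparison",
    "percent_change",
    "predicted_treated_change",
    "compare_groups",
    "correlate",
    "growth_percent_changes",
]

VARIANCE_RATIO_WELCH = 4.0  # F-ratio rule triggering Welch's correction


@dataclass(frozen=True)
class GrowthRecord:
    """Per-animal tumor volume time series with a treatment-day anchor."""

    animal_id: str
    group: str  # "control" | "treated"
    days: tuple[int, ...]
    volumes_mm3: tuple[float, ...]
    treatment_day: int

    def __post_init__(self):
        if len(self.days) != len(self.volumes_mm3):
            raise InvalidBaselineError("days and volumes differ in length")
        if any(v <= 0 for v in self.volumes_mm3):
            raise InvalidBaselineError("volumes must be positive")
        if self.treatment_day not in self.days:
            raise InvalidBaselineError("treatment day missing from series")

    def volume_on(self, day: int) -> float:
        return self.volumes_mm3[self.days.index(day)]


@dataclass(frozen=True)
class GroupComparison:
    group_means: tuple[float, ...]
    group_sems: tuple[float, ...]
    group_ns: tuple[int, ...]
    test: str
    statistic: float
    p_value: float
    transform: str = "none"
    posthoc: pd.DataFrame | None = None


def percent_change(v_t: float, v_0: float) -> float:
    """Percent change of volume relative to a (positive) baseline."""
    if v_0 <= 0:
        raise InvalidBaselineError("baseline volume must be positive")
    return 100.0 * (v_t - v_0) / v_0


def predicted_treated_change(control_change_percent: float,
                             ablation_fraction: float) -> float:
    """Expected treated-arm percent change given control growth and an
    instantaneous ablation of the given tumor fraction at baseline."""
    if control_change_percent <= -100.0:
        raise InvalidBaselineError("control change must exceed -100%")
    if not (0.0 <= ablation_fraction < 1.0):
        raise InvalidFractionError("ablation fraction must lie in [0, 1)")
    growth = 1.0 + control_change_percent / 100.0
    return 100.0 * (growth * (1.0 - ablation_fraction) - 1.0)


def _summaries(groups):
    means = tuple(float(np.mean(g)) for g in groups)
    sems = tuple(float(sps.sem(g)) for g in groups)
    ns = tuple(len(g) for g in groups)
    return means, sems, ns


def compare_groups(*groups, lognormal: bool = False,
                   welch: str | bool = "auto") -> GroupComparison:
    """Two-group t test or one-way ANOVA with Tukey post-hoc.

    For variables declared lognormal the test runs on log10-transformed
    values (summaries are still reported on the original scale).  With two
    groups, Welch's correction applies when forced (``welch=True``) or,
    under the default "auto" rule, when the larger sample variance exceeds
    the smaller by more than a factor of 4.  Three or more groups get a
    one-way ANOVA followed by Tukey's HSD.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    means, sems, ns = _summaries(arrays)
    work = arrays
    transform = "none"
    if lognormal:
        if any(np.any(a <= 0) for a in arrays):
            raise TransformError("log10 transform requires positive values")
        work = [np.log10(a) for a in arrays]
        transform = "log10"
    if len(work) == 2:
        a, b = work
        if welch == "auto":
            va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
            hi, lo = max(va, vb), min(va, vb)
            use_welch = lo == 0 or hi / lo > VARIANCE_RATIO_WELCH
        else:
            use_welch = bool(welch)
        res = sps.ttest_ind(a, b, equal_var=not use_welch)
        name = "welch_t" if use_welch else "student_t"
        return GroupComparison(means, sems, ns, name,
                               float(res.statistic), float(res.pvalue),
                               transform)
    fres = sps.f_oneway(*work)
    tuk = sps.tukey_hsd(*work)
    rows = []
    k = len(work)
    for i in range(k):
        for j in range(i + 1, k):
            rows.append({"group_a": i, "group_b": j,
                         "statistic": float(tuk.statistic[i, j]),
                         "p_value": float(tuk.pvalue[i, j])})
    return GroupComparison(means, sems, ns, "anova_tukey",
                           float(fres.statistic), float(fres.pvalue),
                           transform, pd.DataFrame(rows))


def correlate(x, y):
    """Pearson correlation with its two-sided t-distribution p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def growth_percent_changes(df: pd.DataFrame, day: int) -> pd.DataFrame:
    """Per-animal percent change at ``day`` relative to each animal's
    treatment day, from a tidy growth table
    (animal, group, day, volume_mm3, treatment_day)."""
    rows = []
    for animal, sub in df.groupby("animal"):
        t_day = int(sub["treatment_day"].iloc[0])
        sub = sub.set_index("day")["volume_mm3"]
        if t_day not in sub.index or day not in sub.index:
            continue
        rows.append({
            "animal": animal,
            "group": df[df["animal"] == animal]["group"].iloc[0],
            "percent_change": percent_change(sub.loc[day], sub.loc[t_day]),
        })
    return pd.DataFrame(rows)
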