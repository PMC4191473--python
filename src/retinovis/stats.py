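"""Group comparisons: summary-based t tests and repeated-measures ANOVA.

Published group results often come as ``mean +/- SEM, n`` triplets; the
two-sample t statistic is therefore computed directly from the summaries,

    t = (m1 - m2) / sqrt(sem1**2 + sem2**2),    df = n1 + n2 - 2,

the SEM-quadrature (unpooled-variance) form with pooled degrees of freedom.
A classical pooled-variance alternative is available behind a flag.  The
raw-data entry point computes each cohort's summary and delegates, so the
two routes agree exactly.

The repeated-measures ANOVA tests (a) the between-group effect on subject
means and (b) the within-subject linear trend across ordered conditions,
obtained by projecting each subject's condition profile onto orthonormal
linear-contrast coefficients and testing the projection against the
subject-level error — the df = 1 polynomial contrast that needs no
sphericity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TTestResult",
    "RmAnovaResult",
    "summarize",
    "t_from_summary",
    "t_from_raw",
    "rm_anova_linear",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard error of the mean, and group size of one cohort."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem <= 0:
            raise ValueError("sem must be positive")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    labels: tuple[str, str] = ("group1", "group2")
    method: str = "sem-quadrature"


@dataclass(frozen=True)
class RmAnovaResult:
    F_between: float
    df_between: tuple[int, int]
    p_between: float
    F_linear: float
    df_linear: tuple[int, int]
    p_linear: float


def summarize(values: Sequence[float]) -> GroupSummary:
    """Mean, SEM (sample SD / sqrt(n)), and n of a raw cohort."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values per group")
    return GroupSummary(
        mean=float(x.mean()),
        sem=float(x.std(ddof=1) / np.sqrt(x.size)),
        n=int(x.size),
    )


def t_from_summary(
    g1: GroupSummary,
    g2: GroupSummary,
    pooled: bool = False,
    labels: tuple[str, str] = ("group1", "group2"),
) -> TTestResult:
    """Two-sample t statistic from ``mean +/- SEM, n`` summaries.

    Default is the SEM-quadrature denominator with df = n1 + n2 - 2; with
    ``pooled=True`` the classical pooled-variance denominator is used (same
    df).  The sign follows (mean1 - mean2).
    """
    df = g1.n + g2.n - 2
    if pooled:
        var1 = (g1.sem**2) * g1.n
        var2 = (g2.sem**2) * g2.n
        sp2 = ((g1.n - 1) * var1 + (g2.n - 1) * var2) / df
        denom = np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
        method = "pooled"
    else:
        denom = np.sqrt(g1.sem**2 + g2.sem**2)
        method = "sem-quadrature"
    t = (g1.mean - g2.mean) / denom
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=int(df), p=float(p), labels=labels, method=method)


def t_from_raw(
    values1: Sequence[float],
    values2: Sequence[float],
    pooled: bool = False,
    labels: tuple[str, str] = ("group1", "group2"),
) -> TTestResult:
    """Two-sample t from raw cohorts; summarizes then delegates, exactly."""
    return t_from_summary(summarize(values1), summarize(values2), pooled, labels)


def _linear_contrast(k: int) -> np.ndarray:
    c = np.arange(k, dtype=float) - (k - 1) / 2.0
    return c / np.linalg.norm(c)


def rm_anova_linear(
    data: pd.DataFrame,
    group_col: str = "group",
    subject_col: str = "subject",
    condition_col: str = "condition",
    value_col: str = "value",
    condition_order: Sequence | None = None,
) -> RmAnovaResult:
    """Mixed repeated-measures ANOVA with a linear within-subject contrast.

    ``data`` is long-form: one row per (group, subject, condition).  The
    design must be balanced within subjects (every subject measured at every
    condition, once).  ``condition_order`` fixes the ordering the linear
    contrast is taken over; default is order of first appearance.
    """
    if condition_order is None:
        condition_order = list(dict.fromkeys(data[condition_col]))
    k = len(condition_order)
    if k < 2:
        raise ValueError("need at least 2 ordered conditions")

    wide = data.pivot_table(
        index=[group_col, subject_col],
        columns=condition_col,
        values=value_col,
        aggfunc="count",
    )
    if wide.isna().any().any() or (wide != 1).any().any():
        raise ValueError("unbalanced design: every subject needs every condition once")
    pivot = data.pivot_table(
        index=[group_col, subject_col], columns=condition_col, values=value_col
    )
    y = pivot.reindex(columns=list(condition_order)).to_numpy()
    groups = np.array([g for g, _ in pivot.index])
    n_total = y.shape[0]
    group_labels = list(dict.fromkeys(groups))
    n_groups = len(group_labels)
    if n_groups < 1 or any((groups == g).sum() < 2 for g in group_labels):
        raise ValueError("need >= 2 subjects per group")

    # Between-group effect on subject means (times k: textbook SS scale).
    m = y.mean(axis=1)
    grand = m.mean()
    ss_between = k * sum(
        (groups == g).sum() * (m[groups == g].mean() - grand) ** 2
        for g in group_labels
    )
    ss_within_subj = k * sum(
        ((m[groups == g] - m[groups == g].mean()) ** 2).sum() for g in group_labels
    )
    df_b = (n_groups - 1, n_total - n_groups)
    if df_b[0] == 0:
        f_between, p_between = 0.0, 1.0
    else:
        ms_b = ss_between / df_b[0]
        ms_w = ss_within_subj / df_b[1]
        f_between = 0.0 if ms_b == 0 else (np.inf if ms_w == 0 else ms_b / ms_w)
        p_between = float(sps.f.sf(f_between, *df_b)) if np.isfinite(f_between) else 0.0

    # Within-subject linear trend: orthonormal contrast scores per subject.
    c = _linear_contrast(k)
    # centering each profile first is exact for flat profiles (the contrast
    # is orthogonal to constants, so this changes nothing mathematically)
    L = (y - y.mean(axis=1, keepdims=True)) @ c
    ss_linear = L.sum() ** 2 / n_total
    ss_error = sum(
        ((L[groups == g] - L[groups == g].mean()) ** 2).sum() for g in group_labels
    )
    df_l = (1, n_total - n_groups)
    if ss_linear == 0:
        f_linear = 0.0
    elif ss_error == 0:
        f_linear = np.inf
    else:
        f_linear = ss_linear / (ss_error / df_l[1])
    p_linear = float(sps.f.sf(f_linear, *df_l)) if np.isfinite(f_linear) else 0.0

    return RmAnovaResult(
        F_between=float(f_between),
        df_between=df_b,
        p_between=p_between,
        F_linear=float(f_linear),
        df_linear=df_l,
        p_linear=p_linear,
    )
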