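"""Feeding-experiment morphometric statistics.

Adult traits (birth weight in g, lengths in mm, wing area in mm^2) are
compared across feeding groups with one-way ANOVA and Tukey's HSD, and
between two groups with Student's t -- from raw per-bee measurements or,
when only published summaries (mean, SD, n) are available, directly from
the summary statistics.  The summary path and the raw path agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MorphoSummary", "TestResult", "ttest_from_summary", "ttest_from_raw",
    "anova_oneway", "tukey_hsd", "tukey_q_statistics", "percent_effect",
    "summarize_morpho",
]


@dataclass(frozen=True)
class MorphoSummary:
    """Published-style group summary: mean +/- SD with group size."""

    group: str
    trait: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    estimate: float  # mean difference (or between-group spread for ANOVA)
    kind: str = "t"
    groups: tuple[str, str] | None = None


def ttest_from_summary(
    g1: MorphoSummary, g2: MorphoSummary, pooled: bool = True
) -> TestResult:
    """Two-sided two-sample t-test from (mean, SD, n) summaries.

    ``pooled=True`` is the classical equal-variance Student test with
    df = n1+n2-2; ``pooled=False`` is Welch's test.  With zero variance in
    both groups the p-value degenerates to 1 (equal means) or 0 (below
    numerical resolution, unequal means).
    """
    diff = g1.mean - g2.mean
    if g1.sd == 0.0 and g2.sd == 0.0:
        df = g1.n + g2.n - 2
        return TestResult(statistic=np.inf if diff else 0.0, df=df,
                          p=0.0 if diff else 1.0, estimate=diff,
                          groups=(g1.group, g2.group))
    t, p = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=pooled)
    if pooled:
        df = g1.n + g2.n - 2
    else:  # Welch-Satterthwaite
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return TestResult(statistic=float(t), df=float(df), p=float(p),
                      estimate=diff, groups=(g1.group, g2.group))


def _summary_of(values: Sequence[float], group: str, trait: str) -> MorphoSummary:
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("each sample needs n >= 2")
    return MorphoSummary(group=group, trait=trait, mean=float(x.mean()),
                         sd=float(x.std(ddof=1)), n=int(x.size))


def ttest_from_raw(
    x_values: Sequence[float], y_values: Sequence[float], pooled: bool = True
) -> TestResult:
    """Raw-data twin of :func:`ttest_from_summary` (identical result)."""
    return ttest_from_summary(
        _summary_of(x_values, "x", ""), _summary_of(y_values, "y", ""),
        pooled=pooled)


def anova_oneway(groups: Sequence[Sequence[float]],
                 labels: Sequence[str] | None = None) -> TestResult:
    """One-way fixed-effects ANOVA: F = MSB/MSW with df (k-1, N-k)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    n_total = int(ns.sum())
    grand = float(np.concatenate(arrays).mean())
    ssb = float(sum(n * (a.mean() - grand) ** 2 for n, a in zip(ns, arrays)))
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df = (k - 1, n_total - k)
    if ssw == 0.0:
        f = 0.0 if ssb == 0.0 else np.inf
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        msb, msw = ssb / df[0], ssw / df[1]
        f = msb / msw
        p = float(stats.f.sf(f, *df)) if f > 0 else 1.0
    return TestResult(statistic=float(f), df=df, p=p, estimate=ssb, kind="F")


def tukey_q_statistics(groups: Sequence[Sequence[float]]
                       ) -> tuple[list[tuple[int, int, float, float]], int, int]:
    """Pairwise studentized-range statistics for a one-way layout.

    Returns ``([(i, j, mean_diff, q), ...], k, df_within)`` with
    q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)).  Exposed separately
    so that simulation studies can compare q against a single critical
    value without recomputing the (expensive) studentized-range tail per
    pair.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    dfw = n_total - k
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    msw = ssw / dfw
    out = []
    for i, j in combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        diff = float(a.mean() - b.mean())
        if msw == 0.0:
            q = 0.0 if diff == 0.0 else np.inf
        else:
            se = np.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
            q = float(abs(diff) / se)
        out.append((i, j, diff, q))
    return out, k, dfw


def tukey_hsd(groups: Sequence[Sequence[float]],
              labels: Sequence[str] | None = None,
              alpha: float = 0.05) -> list[TestResult]:
    """Tukey HSD all-pairs comparisons after a one-way layout.

    For each pair, q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)); the
    p-value is the studentized-range upper tail with (k, N-k) parameters.
    """
    if labels is None:
        labels = [f"group{i+1}" for i in range(len(groups))]
    pairs, k, dfw = tukey_q_statistics(groups)
    out = []
    for i, j, diff, q in pairs:
        if np.isinf(q):
            p = 0.0
        elif q == 0.0:
            p = 1.0
        else:
            p = float(stats.studentized_range.sf(q, k, dfw))
        out.append(TestResult(statistic=q, df=(k, dfw), p=min(max(p, 0.0), 1.0),
                              estimate=diff, kind="q",
                              groups=(labels[i], labels[j])))
    return out


def percent_effect(treated: MorphoSummary, control: MorphoSummary) -> float:
    """Relative reduction of the treated mean vs control:
    (control - treated) / control."""
    if control.mean == 0:
        raise ValueError("control mean must be nonzero")
    return (control.mean - treated.mean) / control.mean


def summarize_morpho(raw: pd.DataFrame, group_col: str = "group",
                     id_col: str = "bee_id") -> list[MorphoSummary]:
    """Per-group, per-trait (mean, SD, n) summaries of a raw per-bee table."""
    traits = [c for c in raw.columns if c not in (group_col, id_col)]
    out = []
    for group, sub in raw.groupby(group_col, sort=True):
        for trait in traits:
            out.append(_summary_of(sub[trait].to_numpy(), str(group), trait))
    return out
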