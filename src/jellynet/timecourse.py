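"""Three-day jelly miRNA time-course analysis.

Raw two-channel intensities are LOWESS-normalized on the MA scale,
concentrations are rescaled so that every miRNA's royal-jelly day-4 mean
is 1, day-to-day changes are assessed with paired t-tests, and each
(miRNA, jelly) series is classified into a qualitative trend shape:
persistent or transient increase, a day-5 dip, a persistent fall, or a
drop that then stays stable (the characteristic royal-jelly pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

__all__ = [
    "TimeCourse", "TrendCall", "lowess_normalize", "scale_to_reference",
    "daypair_tests", "classify_trend", "classify_trends",
]

DAYS = (4, 5, 6)


@dataclass
class TimeCourse:
    """Long-format concentration series.

    ``data`` columns: mirna, jelly ("WJ"/"RJ"), day (4/5/6), replicate,
    value.  ``scale`` is "raw" or "relative"; relative data have each
    miRNA's RJ day-4 replicate mean equal to 1.
    """

    data: pd.DataFrame
    scale: str = "raw"
    excluded: list[str] = field(default_factory=list)

    def cell(self, mirna: str, jelly: str, day: int) -> np.ndarray:
        d = self.data
        sel = d[(d["mirna"] == mirna) & (d["jelly"] == jelly) & (d["day"] == day)]
        return sel.sort_values("replicate")["value"].to_numpy()

    def series_keys(self) -> list[tuple[str, str]]:
        return sorted({(m, j) for m, j in zip(self.data["mirna"], self.data["jelly"])})


def lowess_normalize(
    ch1: np.ndarray,
    ch2: np.ndarray,
    span: float = 0.4,
    iterations: int = 2,
    floor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity-dependent (MA) normalization of two-channel data.

    After clamping background-subtracted intensities at ``floor``, computes
    M = log2(ch1/ch2) and A = mean log2 intensity, fits a locally weighted
    regression of M on A (tri-cube weights, ``span`` fraction of points,
    ``iterations`` robustness iterations) and returns (M - fit, A).
    """
    x1 = np.maximum(np.asarray(ch1, dtype=float), floor)
    x2 = np.maximum(np.asarray(ch2, dtype=float), floor)
    if x1.shape != x2.shape:
        raise ValueError("channel arrays must have the same shape")
    if x1.size < 10:
        raise ValueError("at least 10 probes required for LOWESS normalization")
    m = np.log2(x1 / x2)
    a = 0.5 * np.log2(x1 * x2)
    fit = sm_lowess(m, a, frac=span, it=iterations, return_sorted=False)
    return m - fit, a


def scale_to_reference(tc: TimeCourse, ref_jelly: str = "RJ", ref_day: int = 4
                       ) -> TimeCourse:
    """Divide every value by its miRNA's reference-cell replicate mean.

    The reference defaults to royal jelly on day 4, so relative
    concentrations read directly as fold differences from that point.
    miRNAs with a zero (or missing) reference are excluded and flagged.
    Idempotent: already-relative data are returned unchanged.
    """
    if tc.scale == "relative":
        return tc
    parts = []
    excluded = []
    for mirna, sub in tc.data.groupby("mirna", sort=True):
        ref = sub[(sub["jelly"] == ref_jelly) & (sub["day"] == ref_day)]["value"]
        denom = float(ref.mean()) if len(ref) else 0.0
        if denom <= 0:
            excluded.append(str(mirna))
            continue
        out = sub.copy()
        out["value"] = out["value"] / denom
        parts.append(out)
    data = pd.concat(parts, ignore_index=True) if parts else tc.data.iloc[0:0].copy()
    return TimeCourse(data=data, scale="relative", excluded=excluded)


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        # zero-variance differences: certainty (p below numerical
        # resolution) or perfect equality
        return 1.0 if float(np.mean(d)) == 0.0 else 0.0
    t = float(np.mean(d)) / (sd / np.sqrt(len(d)))
    return float(2.0 * stats.t.sf(abs(t), len(d) - 1))


def daypair_tests(tc: TimeCourse, paired: bool = True, alpha: float = 0.05
                  ) -> pd.DataFrame:
    """Two-sided paired t-tests for every (miRNA, jelly) day pair.

    Pairing is by replicate index; unequal replicate counts are an error
    in paired mode.  Returns columns mirna, jelly, day_a, day_b, p,
    significant.
    """
    rows = []
    for mirna, jelly in tc.series_keys():
        cells = {d: tc.cell(mirna, jelly, d) for d in DAYS}
        for da, db in combinations(DAYS, 2):
            a, b = cells[da], cells[db]
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"need >=2 replicates for {mirna}/{jelly}")
            if paired:
                if len(a) != len(b):
                    raise ValueError(
                        f"unequal replicate counts for {mirna}/{jelly} "
                        f"day {da} vs {db} with paired=True")
                p = _paired_p(a, b)
            else:
                p = float(stats.ttest_ind(a, b).pvalue)
            rows.append((mirna, jelly, da, db, p, p < alpha))
    return pd.DataFrame(
        rows, columns=["mirna", "jelly", "day_a", "day_b", "p", "significant"])


@dataclass(frozen=True)
class TrendCall:
    mirna: str
    jelly: str
    trend: str
    pvalues: tuple[float, float, float]  # (d4-d5, d5-d6, d4-d6)


def classify_trend(
    means: tuple[float, float, float],
    pvals: Mapping[tuple[int, int], float],
    alpha: float = 0.05,
) -> str:
    """Qualitative trend shape from day means and day-pair p-values.

    Rules, in order:
      persistent_increase: d5 > d4, d6 >= d5, d4->d6 change significant
      transient_increase:  d5 > d4 significant AND d6 < d5 significant
      dip:                 d5 < d4 significant AND d6 > d5 significant
      drop_then_stable:    d5 < d4 significant AND d5->d6 not significant
      persistent_fall:     d5 < d4, d6 <= d5, d4->d6 change significant
      none otherwise.

    drop_then_stable is tested before persistent_fall because the two
    overlap whenever the stable tail samples slightly below day 5; the
    day5->day6 significance test is what discriminates a genuine continued
    fall from a stable plateau.
    """
    d4, d5, d6 = means
    p45 = pvals[(4, 5)]
    p56 = pvals[(5, 6)]
    p46 = pvals[(4, 6)]
    if d5 > d4 and d6 >= d5 and p46 < alpha:
        return "persistent_increase"
    if d5 > d4 and p45 < alpha and d6 < d5 and p56 < alpha:
        return "transient_increase"
    if d5 < d4 and p45 < alpha and d6 > d5 and p56 < alpha:
        return "dip"
    if d5 < d4 and p45 < alpha and p56 >= alpha:
        return "drop_then_stable"
    if d5 < d4 and d6 <= d5 and p46 < alpha:
        return "persistent_fall"
    return "none"


def classify_trends(tc: TimeCourse, alpha: float = 0.05) -> list[TrendCall]:
    """Classify every (miRNA, jelly) series of a relative time course."""
    if tc.scale != "relative":
        tc = scale_to_reference(tc)
    tests = daypair_tests(tc, paired=True, alpha=alpha)
    calls = []
    for mirna, jelly in tc.series_keys():
        means = tuple(float(np.mean(tc.cell(mirna, jelly, d))) for d in DAYS)
        sub = tests[(tests["mirna"] == mirna) & (tests["jelly"] == jelly)]
        pv = {(int(r["day_a"]), int(r["day_b"])): float(r["p"])
              for _, r in sub.iterrows()}
        trend = classify_trend(means, pv, alpha=alpha)
        calls.append(TrendCall(
            mirna=mirna, jelly=jelly, trend=trend,
            pvalues=(pv[(4, 5)], pv[(5, 6)], pv[(4, 6)])))
    return calls
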