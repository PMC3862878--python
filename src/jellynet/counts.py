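"""Count-based differential statistics for two sequencing libraries.

The central test is the Audic-Claverie exact test: given a feature observed
``x`` times in a library of ``N1`` tags and ``y`` times in a library of
``N2`` tags, the distribution of ``y`` conditional on ``x`` under equal
underlying concentrations is the posterior predictive

    p(y | x) = r^y * (x+y)! / (x! * y! * (1+r)^(x+y+1)),   r = N2/N1,

a negative-binomial mass in ``y``.  Two-sided significance is the doubled
smaller tail, capped at 1.  Everything is evaluated in log space so that
counts in the millions do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

import pandas as pd

__all__ = [
    "CountPair", "DiffResult", "ac_pvalue", "fold_change", "bh_adjust",
    "diff_table", "de_genes", "target_overlap",
]


@dataclass(frozen=True)
class CountPair:
    """A feature's counts in two libraries, with the library sizes."""

    feature: str
    x: int
    y: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"negative count for {self.feature!r}")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library sizes must be positive")


@dataclass(frozen=True)
class DiffResult:
    feature: str
    fold_change: float
    p: float
    q: float
    direction: str  # "up_in_1" | "up_in_2" | "none"


def _ac_log_pmf(x: int, ks: np.ndarray, log_r: float) -> np.ndarray:
    # log p(k|x) = k log r + lgamma(x+k+1) - lgamma(x+1) - lgamma(k+1)
    #              - (x+k+1) log(1+r)
    log1pr = np.logaddexp(0.0, log_r)
    return (
        ks * log_r
        + gammaln(x + ks + 1)
        - gammaln(x + 1)
        - gammaln(ks + 1)
        - (x + ks + 1) * log1pr
    )


def ac_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts ``x`` vs ``y``.

    The lower tail sums ``p(k|x)`` for ``k <= y``; the upper tail is
    ``1 - sum_{k < y}`` with a non-negativity clamp.  The two-sided p is
    ``min(1, 2 * min(lower, upper))``.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    log_r = float(np.log(n2) - np.log(n1))
    ks = np.arange(y + 1)
    log_terms = _ac_log_pmf(x, ks, log_r)
    lower = float(np.exp(logsumexp(log_terms)))
    below = float(np.exp(logsumexp(log_terms[:-1]))) if y > 0 else 0.0
    upper = max(0.0, 1.0 - below)
    return min(1.0, 2.0 * min(lower, upper))


def fold_change(
    x: int, y: int, n1: int, n2: int, pseudocount: float = 0.5
) -> float:
    """Library-size-normalized fold change ``((x+pc)/N1) / ((y+pc)/N2)``.

    The pseudocount keeps the ratio finite when one count is zero; the
    default 0.5 is the conventional half-count continuity correction.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    return ((x + pseudocount) / n1) / ((y + pseudocount) / n2)


def _direction(fc: float) -> str:
    if fc > 1.0:
        return "up_in_1"
    if fc < 1.0:
        return "up_in_2"
    return "none"


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def diff_table(
    pairs: Iterable[CountPair], pseudocount: float = 0.5
) -> pd.DataFrame:
    """Full differential table: fold change, AC p, BH q and direction.

    Returns a DataFrame indexed by feature with columns
    ``x, y, n1, n2, fold_change, p, q, direction``.
    """
    pairs = list(pairs)
    rows = []
    for cp in pairs:
        fc = fold_change(cp.x, cp.y, cp.n1, cp.n2, pseudocount)
        p = ac_pvalue(cp.x, cp.y, cp.n1, cp.n2)
        rows.append((cp.feature, cp.x, cp.y, cp.n1, cp.n2, fc, p, _direction(fc)))
    df = pd.DataFrame(
        rows, columns=["feature", "x", "y", "n1", "n2", "fold_change", "p", "direction"]
    ).set_index("feature")
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df[["x", "y", "n1", "n2", "fold_change", "p", "q", "direction"]]


def de_genes(
    pairs: Iterable[CountPair],
    ratio_thresh: float = 2.0,
    p_thresh: float = 0.01,
    pseudocount: float = 0.5,
) -> dict:
    """Differential-expression call: flagged iff |fold| > ratio and p < p_thresh.

    The fold criterion is direction-agnostic (``max(fc, 1/fc) > ratio_thresh``);
    the returned dict partitions flagged features into ``up`` (higher in
    library 1) and ``down`` and carries the full table.
    """
    table = diff_table(pairs, pseudocount)
    if len(table):
        mag = np.maximum(table["fold_change"], 1.0 / table["fold_change"])
        flagged = table[(mag > ratio_thresh) & (table["p"] < p_thresh)]
    else:
        flagged = table
    up = set(flagged.index[flagged["direction"] == "up_in_1"])
    down = set(flagged.index[flagged["direction"] == "up_in_2"])
    return {
        "table": table,
        "de": up | down,
        "up": up,
        "down": down,
        "n_de": len(up) + len(down),
    }


def target_overlap(
    de_result: dict,
    target_set: set,
    expressed_set: set,
    p_thresh: float = 0.05,
    strong_fold: float = 2.0,
) -> dict:
    """Overlap accounting between a predicted target set and a DE table.

    Reports target counts, targets among the expressed universe, and --
    among expressed targets -- how many move up or down at ``p_thresh``,
    plus the strongly-down subset (fold beyond ``strong_fold``).
    """
    table: pd.DataFrame = de_result["table"]
    targets = set(target_set)
    expressed = set(expressed_set)
    hit = targets & expressed
    present = table.loc[[f for f in table.index if f in hit]]
    sig = present[present["p"] < p_thresh]
    up = sig[sig["direction"] == "up_in_1"]
    down = sig[sig["direction"] == "up_in_2"]
    strong_down = down[1.0 / down["fold_change"] > strong_fold]
    return {
        "n_targets": len(targets),
        "n_expressed_targets": len(hit),
        "n_up": len(up),
        "n_down": len(down),
        "n_strong_down": len(strong_down),
        "up": set(up.index),
        "down": set(down.index),
        "strong_down": set(strong_down.index),
    }
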