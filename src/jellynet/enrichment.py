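"""Hypergeometric over-representation of term sets in a query gene set.

For a universe of N genes of which K carry a term, and a query of n genes
with k term genes, significance is the upper hypergeometric tail
P(X >= k).  BH correction is applied across all tested terms.  Term sets
come from GMT files (term, description, member genes, tab-separated).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from jellynet.counts import bh_adjust

__all__ = ["EnrichmentResult", "enrich", "read_gmt", "write_gmt"]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    N: int
    K: int
    n: int
    k: int
    p: float
    q: float


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: ``term<TAB>description<TAB>gene1<TAB>gene2...``."""
    terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = {g for g in parts[2:] if g}
    return terms


def write_gmt(terms: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "synthetic") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term in sorted(terms):
            genes = "\t".join(sorted(terms[term]))
            fh.write(f"{term}\t{description}\t{genes}\n")


def enrich(
    query_set: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of each term in the query.

    Term sets are intersected with the universe before testing; the query
    must be a subset of the universe.  Terms with zero overlap are reported
    with p = 1.  Results are sorted by increasing p.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(query_set)
    if not query <= uni:
        raise ValueError("query set must be contained in the universe")
    N, n = len(uni), len(query)
    rows = []
    for term in sorted(term_sets):
        genes = set(term_sets[term]) & uni
        K = len(genes)
        k = len(genes & query)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, N, K, n, k, min(p, 1.0)))
    qvals = bh_adjust([r[5] for r in rows]) if rows else []
    results = [
        EnrichmentResult(term=t, N=N, K=K, n=n, k=k, p=p, q=float(q))
        for (t, N, K, n, k, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
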