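"""miRNA->mRNA target maps, the anti-correlation regulatory network,
MCODE-style dense-module detection, and the co-targeting statistic.

The network rule: keep a predicted miRNA->target edge when the miRNA is
significantly more concentrated in worker jelly AND its target is
significantly down-regulated in worker larvae (or the exact mirror), on
the logic that food-borne miRNAs repress their targets in the larvae that
eat that food.

Module detection re-implements the MCODE algorithm: each vertex is
weighted by the highest k-core of its closed neighborhood (core number
times core density), modules grow greedily from high-weight seeds, and are
ranked by density x size.

Co-targeting: the chance that one mRNA is hit by >= k of m chosen miRNAs
under independent targeting (miRNA i hits a given mRNA with probability
|T_i|/N) is a Poisson-binomial tail, computed by exact dynamic
programming; the number of such mRNAs in the universe is modelled Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TargetMap", "RegulatoryNetwork", "Module", "CoTargetStat",
    "seed_match_targets", "select_concordant_pairs", "build_network",
    "mcode_vertex_weights", "mcode_modules", "cotarget_stat",
    "poisson_binomial_tail",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TargetMap:
    """Bipartite miRNA -> {mRNA} relation over a declared mRNA universe."""

    universe: set[str] = field(default_factory=set)
    targets: dict[str, set[str]] = field(default_factory=dict)

    def add(self, mirna: str, mrna: str) -> None:
        if mrna not in self.universe:
            raise ValueError(f"{mrna!r} not in declared universe")
        self.targets.setdefault(mirna, set()).add(mrna)

    def n_targets(self, mirna: str) -> int:
        return len(self.targets.get(mirna, set()))

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self.targets.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for m in sorted(self.targets):
                for g in sorted(self.targets[m]):
                    fh.write(f"{m}\t{g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, universe: Iterable[str] | None = None
                 ) -> "TargetMap":
        """Read a ``mirna<TAB>mrna`` edge list; the universe defaults to the
        mRNAs appearing in the file."""
        pairs = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                m, g = line.split("\t")
                pairs.append((m, g))
        uni = set(universe) if universe is not None else {g for _, g in pairs}
        tmap = cls(universe=uni)
        for m, g in pairs:
            tmap.add(m, g)
        return tmap


def seed_match_targets(
    mirna_seqs: Mapping[str, str],
    utr_seqs: Mapping[str, str],
    seed_span: tuple[int, int] = (2, 8),
) -> TargetMap:
    """Deterministic seed-match target prediction.

    An edge is called when the reverse complement of the miRNA seed
    (1-based positions ``seed_span``, default 2-8) occurs as a substring of
    the mRNA 3'UTR.  Sequences are normalized to DNA (U->T, uppercase).
    """
    lo, hi = seed_span
    if lo < 1 or hi < lo:
        raise ValueError("invalid seed span")
    tmap = TargetMap(universe=set(utr_seqs))
    utrs = {g: s.upper().replace("U", "T") for g, s in utr_seqs.items()}
    for mirna, seq in mirna_seqs.items():
        seq = seq.upper().replace("U", "T")
        if len(seq) < hi:
            raise ValueError(f"miRNA {mirna!r} shorter than seed span")
        site = _revcomp(seq[lo - 1:hi])
        for gene, utr in utrs.items():
            if site in utr:
                tmap.add(mirna, gene)
        tmap.targets.setdefault(mirna, set())
    return tmap


def select_concordant_pairs(
    mirna_diff: pd.DataFrame,
    mrna_diff: pd.DataFrame,
    tmap: TargetMap,
    fold_thresh: float = 2.0,
    p_thresh: float = 0.01,
) -> list[tuple[str, str, int]]:
    """Anti-correlated miRNA-target pairs.

    ``mirna_diff`` is the worker-vs-royal jelly differential table
    (library 1 = worker jelly) and ``mrna_diff`` the worker-vs-queen larval
    table (library 1 = worker larvae); both are ``diff_table`` outputs.  An
    edge survives when the miRNA is significantly jelly-enriched in one
    direction and its target significantly shifted the *opposite* way in
    the larvae.  Sign +1 marks (worker-jelly-high, worker-larva-down),
    -1 the mirror.
    """
    def calls(df: pd.DataFrame) -> dict[str, str]:
        out = {}
        for feat, row in df.iterrows():
            fc, p = row["fold_change"], row["p"]
            if p < p_thresh and max(fc, 1.0 / fc) >= fold_thresh:
                out[feat] = "up" if fc > 1 else "down"
        return out

    mirna_call = calls(mirna_diff)
    mrna_call = calls(mrna_diff)
    kept: list[tuple[str, str, int]] = []
    for mirna in sorted(tmap.targets):
        mc = mirna_call.get(mirna)
        if mc is None:
            continue
        for gene in sorted(tmap.targets[mirna]):
            gc = mrna_call.get(gene)
            if gc is None:
                continue
            if mc == "up" and gc == "down":
                kept.append((mirna, gene, +1))
            elif mc == "down" and gc == "up":
                kept.append((mirna, gene, -1))
    return kept


@dataclass
class RegulatoryNetwork:
    """Signed bipartite miRNA-mRNA graph (only connected nodes counted)."""

    graph: nx.Graph

    @property
    def node_count(self) -> int:
        return sum(1 for n in self.graph if self.graph.degree(n) > 0)

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def mirnas(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("bipartite") == 0}

    def mrnas(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("bipartite") == 1}


def build_network(edges: Iterable[tuple[str, str, int]]) -> RegulatoryNetwork:
    """Assemble the deduplicated signed bipartite network from kept pairs."""
    g = nx.Graph()
    for mirna, mrna, sign in edges:
        if g.has_node(mirna) and g.nodes[mirna].get("bipartite") == 1:
            raise ValueError(f"{mirna!r} appears on both sides of the bipartition")
        if g.has_node(mrna) and g.nodes[mrna].get("bipartite") == 0:
            raise ValueError(f"{mrna!r} appears on both sides of the bipartition")
        g.add_node(mirna, bipartite=0)
        g.add_node(mrna, bipartite=1)
        g.add_edge(mirna, mrna, sign=int(sign))
    return RegulatoryNetwork(g)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def mcode_vertex_weights(g: nx.Graph) -> dict:
    """MCODE vertex weighting.

    For each vertex, take the subgraph induced by its closed neighborhood,
    find that subgraph's highest k-core, and weight the vertex by
    (core number) x (density of the core).
    """
    weights = {}
    for v in g:
        nbhd = list(g.neighbors(v)) + [v]
        sub = g.subgraph(nbhd)
        core_num = nx.core_number(sub)
        kmax = max(core_num.values())
        if kmax == 0:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, c in core_num.items() if c >= kmax]
        weights[v] = kmax * _density(g.subgraph(core_nodes))
    return weights


@dataclass
class Module:
    """A dense subnetwork found by MCODE."""

    vertices: set
    seed: object
    score: float
    weights: dict

    @property
    def size(self) -> int:
        return len(self.vertices)


def mcode_modules(
    net: RegulatoryNetwork | nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_thresh: float = 0.2,
) -> list[Module]:
    """MCODE molecular-complex detection.

    Seeds are unvisited vertices in decreasing weight order (ties broken by
    node id for determinism).  Expansion adds neighbors whose weight is at
    least ``seed_weight * (1 - vwp)``, branching recursively; vertices
    added to a complex are never re-used (first-seed-wins exclusivity),
    while examined-but-rejected neighbors stay available to later seeds.  ``haircut`` removes singly-connected module vertices;
    ``fluff`` optionally adds boundary neighbors whose neighborhood density
    exceeds ``fluff_thresh``.  Modules are ranked by score =
    density x size; single vertices and edgeless candidates are dropped.
    """
    g = net.graph if isinstance(net, RegulatoryNetwork) else net
    if g.number_of_nodes() == 0:
        return []
    weights = mcode_vertex_weights(g)
    order = sorted(g.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    modules: list[Module] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        stack = [seed]
        seen = {seed}
        while stack:
            v = stack.pop()
            for u in sorted(g.neighbors(v), key=str):
                if u in seen or u in assigned:
                    continue
                seen.add(u)
                if weights[u] >= threshold:
                    members.add(u)
                    stack.append(u)
        # only vertices actually added to the complex are consumed;
        # examined-but-rejected neighbors stay available to later seeds
        assigned |= members
        if haircut:
            sub = g.subgraph(members)
            members = {v for v in members if sub.degree(v) >= 2}
        if fluff:
            extra = set()
            for v in list(members):
                for u in g.neighbors(v):
                    if u in members or u in extra:
                        continue
                    nbhd = list(g.neighbors(u)) + [u]
                    if _density(g.subgraph(nbhd)) > fluff_thresh:
                        extra.add(u)
            members |= extra
        sub = g.subgraph(members)
        if len(members) < 2 or sub.number_of_edges() == 0:
            continue
        score = _density(sub) * len(members)
        modules.append(Module(
            vertices=set(members), seed=seed, score=score,
            weights={v: weights[v] for v in members}))
    modules.sort(key=lambda m: (-m.score, str(m.seed)))
    return modules


def poisson_binomial_tail(probs: Sequence[float], k: int) -> float:
    """P(sum of independent Bernoulli(p_i) >= k) by exact DP."""
    p = np.asarray(probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if k <= 0:
        return 1.0
    if k > len(p):
        return 0.0
    pmf = np.zeros(len(p) + 1)
    pmf[0] = 1.0
    for pi in p:
        pmf[1:] = pmf[1:] * (1 - pi) + pmf[:-1] * pi
        pmf[0] *= 1 - pi
    return float(pmf[k:].sum())


@dataclass
class CoTargetStat:
    """Probability accounting for k-of-m co-targeting of a single mRNA."""

    m: int
    k: int
    probs: tuple[float, ...]
    p_single: float
    expected_cases: float
    observed_cases: int
    p_multi: float


def cotarget_stat(
    tmap: TargetMap,
    top_mirnas: Sequence[str],
    k: int,
    observed_cases: int,
) -> CoTargetStat:
    """Significance of observing ``observed_cases`` mRNAs each targeted by
    at least ``k`` of the ``top_mirnas``.

    Null model: miRNA i targets any given mRNA independently with
    probability |T_i| / N.  p_single is the Poisson-binomial tail; the
    count of co-targeted mRNAs in the universe is taken Poisson with mean
    N * p_single, and p_multi is its upper tail at the observed count.
    """
    m = len(top_mirnas)
    if k > m:
        raise ValueError("k cannot exceed the number of miRNAs")
    missing = [x for x in top_mirnas if x not in tmap.targets]
    if missing:
        raise ValueError(f"miRNAs absent from target map: {missing}")
    n_universe = len(tmap.universe)
    if n_universe == 0:
        raise ValueError("empty mRNA universe")
    probs = tuple(tmap.n_targets(x) / n_universe for x in top_mirnas)
    p_single = poisson_binomial_tail(probs, k)
    mu = n_universe * p_single
    p_multi = float(stats.poisson.sf(observed_cases - 1, mu)) if observed_cases > 0 else 1.0
    return CoTargetStat(
        m=m, k=k, probs=probs, p_single=p_single,
        expected_cases=mu, observed_cases=observed_cases, p_multi=p_multi)
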