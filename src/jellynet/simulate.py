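"""Synthetic jelly small-RNA study generator with planted ground truth.

Every input the analysis chain consumes can be generated here: an
annotation catalog, worker/royal jelly tag libraries with a planted global
miRNA depletion, a three-day concentration time course with planted trend
shapes, a miRNA->mRNA target map with planted co-targeted modules, a
two-condition larval mRNA count table with planted repression of the
targets of jelly-abundant miRNAs, and per-bee morphometric tables with
planted treatment effects.

The emulated structure follows the real study libraries: worker jelly is
dominated by miRNAs (~51% of reads) with tRNA fragments at ~17%, royal
jelly is miRNA-poor (~2%) and tRNA-rich (~48%), and individual miRNA
concentrations in royal jelly sit globally 7-215-fold below worker jelly.

Determinism: a single integer seed drives one explicit RNG stream per
operation (derived sub-seeds), so any artifact can be regenerated
independently of the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from jellynet.network import TargetMap
from jellynet.profiling import Catalog, TagLibrary

__all__ = [
    "SimConfig", "GroundTruth", "gen_annotation", "gen_utrs",
    "gen_jelly_libraries", "gen_target_map", "gen_timecourse",
    "gen_larval_expression", "gen_morpho", "gen_term_sets",
]

TREND_CLASSES = (
    "persistent_increase", "transient_increase", "dip",
    "persistent_fall", "drop_then_stable", "none",
)

# fixed sub-stream ids so each operation has its own reproducible RNG
_STREAMS = {
    "annotation": 1, "jelly": 2, "timecourse": 3, "expression": 4,
    "morpho": 5, "targets": 6, "utrs": 7, "terms": 8,
}

_DEFAULT_COMPOSITION_WJ = {
    "known_miRNA": 0.51, "tRNA": 0.17, "other_ncRNA": 0.06,
    "genic_mRNA": 0.0, "unannotated": 0.26,
}
_DEFAULT_COMPOSITION_RJ = {
    "known_miRNA": 0.02, "tRNA": 0.48, "other_ncRNA": 0.09,
    "genic_mRNA": 0.0, "unannotated": 0.41,
}
# worker-jelly trend class counts mirror the microarray time course
# (persistent/transient increase, day-5 dip, persistent fall)
_DEFAULT_TRENDS = {
    "persistent_increase": 28, "transient_increase": 15,
    "dip": 25, "persistent_fall": 9,
}
# treated-vs-control relative shifts for the six adult traits
_DEFAULT_MORPHO_EFFECTS = {
    "birth_weight": -0.08, "body_length": -0.05, "proboscis_length": 0.03,
    "wing_length": -0.03, "wing_width": -0.05, "wing_area": -0.07,
}
# control-group trait means/SDs (g, mm, mm^2); weight/length/area follow the
# published queen summaries, the remaining traits use realistic queen values
_DEFAULT_MORPHO_CONTROL = {
    "birth_weight": (0.2355, 0.02),
    "body_length": (18.0737, 1.038),
    "proboscis_length": (6.5, 0.25),
    "wing_length": (9.3, 0.35),
    "wing_width": (3.15, 0.14),
    "wing_area": (20.4017, 1.0491),
}


@dataclass
class SimConfig:
    """Study-level configuration for all generators.

    The defaults are the emulated study conditions; override individual
    fields for scaled-down test scenarios.
    """

    seed: int = 0
    n_mirna_genes: int = 77
    n_trna: int = 150
    n_other_nc: int = 100
    n_mrna: int = 2000
    library_size_wj: int = 2_000_000
    library_size_rj: int = 2_000_000
    composition_wj: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMPOSITION_WJ))
    composition_rj: dict[str, float] | None = field(
        default_factory=lambda: dict(_DEFAULT_COMPOSITION_RJ))
    depletion_factor: float = 38.8           # geometric centre of 7-215x
    fold_range: tuple[float, float] = (7.0, 215.0)
    mirna_abundance_sigma: float = 2.0       # log-normal spread of miRNA levels
    max_isoforms: int = 3
    utr_length: int = 500
    targets_per_mirna: tuple[int, int] = (50, 150)
    n_planted_modules: int = 4
    module_mirnas: int = 5
    module_mrnas: int = 10
    repression_factor: float = 1/3
    expression_depth: int = 1_000_000
    timecourse_trends: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_TRENDS))
    rj_drop_range: tuple[float, float] = (2.6, 64.0)
    timecourse_replicates: int = 6
    timecourse_noise_sd: float = 0.05        # SD of log concentration
    morpho_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MORPHO_EFFECTS))
    morpho_control: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MORPHO_CONTROL))
    group_ns: dict[str, int] = field(
        default_factory=lambda: {"untreated": 57, "control": 57, "treated": 64})

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.composition_wj.values()) - 1.0) > 1e-9:
            raise ValueError("composition_wj must sum to 1")
        if self.composition_rj is not None:
            if abs(sum(self.composition_rj.values()) - 1.0) > 1e-9:
                raise ValueError("composition_rj must sum to 1")
        if self.depletion_factor < 1:
            raise ValueError("depletion_factor must be >= 1")
        lo, hi = self.fold_range
        if not (0 < lo <= hi):
            raise ValueError("fold_range must satisfy 0 < lo <= hi")
        for name in ("n_mirna_genes", "n_trna", "n_other_nc", "n_mrna",
                     "library_size_wj", "library_size_rj"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if sum(self.timecourse_trends.values()) > self.n_mirna_genes:
            raise ValueError("trend counts exceed n_mirna_genes")
        for cls in self.timecourse_trends:
            if cls not in TREND_CLASSES:
                raise ValueError(f"unknown trend class {cls!r}")
        for n in self.group_ns.values():
            if n < 2:
                raise ValueError("each feeding group needs n >= 2")

    def rng(self, stream: str) -> np.random.Generator:
        """Operation-specific RNG derived from the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class GroundTruth:
    """Planted truth recorded alongside the generated artifacts."""

    true_ratios: dict[str, float] = field(default_factory=dict)
    tag_categories: dict[str, str] = field(default_factory=dict)
    tag_features: dict[str, str] = field(default_factory=dict)
    trend_labels: dict[str, str] = field(default_factory=dict)  # "mirna|jelly"
    target_edges: list[tuple[str, str]] = field(default_factory=list)
    planted_modules: list[dict] = field(default_factory=list)
    repressed_genes: list[str] = field(default_factory=list)
    true_mrna_ratios: dict[str, float] = field(default_factory=dict)
    trait_means: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _random_seqs(rng: np.random.Generator, n: int, lengths: np.ndarray,
                 taken: set[str]) -> list[str]:
    """Unique random DNA sequences not colliding with ``taken``."""
    alphabet = np.array(list("ACGT"))
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        L = int(lengths[len(out) % len(lengths)])
        seq = "".join(alphabet[rng.integers(0, 4, size=L)])
        if seq not in taken:
            taken.add(seq)
            out.append(seq)
        else:
            attempts += 1
            if attempts > 50 * n + 1000:
                raise ValueError(
                    "requested catalog size exceeds available unique k-mer space")
    return out


def gen_annotation(cfg: SimConfig) -> Catalog:
    """Random annotation catalog over the DNA alphabet, lengths 18-30.

    Sequences are unique across all categories; each miRNA gene receives
    1..max_isoforms isoform sequences.
    """
    rng = cfg.rng("annotation")
    taken: set[str] = set()
    cat = Catalog()
    # miRNA isoforms: typical mature lengths
    for i in range(cfg.n_mirna_genes):
        gene = f"mir-{i+1:03d}"
        n_iso = int(rng.integers(1, cfg.max_isoforms + 1))
        lengths = rng.integers(20, 24, size=n_iso)
        for seq in _random_seqs(rng, n_iso, lengths, taken):
            cat.add("known_miRNA", seq, gene)
    for i, seq in enumerate(
            _random_seqs(rng, cfg.n_trna, rng.integers(18, 31, size=max(cfg.n_trna, 1)), taken)):
        cat.add("tRNA", seq, f"trna-{i+1:03d}")
    for i, seq in enumerate(
            _random_seqs(rng, cfg.n_other_nc, rng.integers(18, 31, size=max(cfg.n_other_nc, 1)), taken)):
        cat.add("other_ncRNA", seq, f"ncrna-{i+1:03d}")
    # genic tags: one tag-length fragment per annotated mRNA gene
    for i, seq in enumerate(
            _random_seqs(rng, cfg.n_mrna, rng.integers(18, 31, size=max(cfg.n_mrna, 1)), taken)):
        cat.add("genic_mRNA", seq, _mrna_id(i))
    return cat


def _mrna_id(i: int) -> str:
    return f"gene-{i+1:04d}"


def mrna_universe(cfg: SimConfig) -> list[str]:
    return [_mrna_id(i) for i in range(cfg.n_mrna)]


def gen_utrs(cfg: SimConfig) -> dict[str, str]:
    """Random 3'UTR sequence per mRNA gene (for the seed matcher)."""
    rng = cfg.rng("utrs")
    alphabet = np.array(list("ACGT"))
    return {
        _mrna_id(i): "".join(alphabet[rng.integers(0, 4, size=cfg.utr_length)])
        for i in range(cfg.n_mrna)
    }


def _lognormal_weights(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    if n == 0:
        return np.array([])
    w = np.exp(rng.normal(0.0, sigma, size=n))
    return w / w.sum()


def gen_jelly_libraries(
    cfg: SimConfig, catalog: Catalog
) -> tuple[TagLibrary, TagLibrary, GroundTruth]:
    """Worker- and royal-jelly tag libraries with a planted global depletion.

    Worker-jelly category shares follow ``composition_wj``; within the
    miRNA category, gene concentrations are log-normal (several orders of
    magnitude).  Each miRNA's true worker/royal concentration ratio is
    ``depletion_factor`` times a log-uniform jitter normalized to geometric
    mean 1 over ``fold_range`` -- so the global (median) fold equals the
    depletion factor on the normalized (per-million) scale.  The royal-jelly
    miRNA category share follows from those ratios; the remaining royal
    mass is split over the other categories in the proportions of
    ``composition_rj`` (or of ``composition_wj`` when not given).

    Returns the two libraries plus the recorded ground truth.
    """
    rng = cfg.rng("jelly")
    truth = GroundTruth()

    mirna_genes = sorted(catalog.features("known_miRNA"))
    # per-gene worker concentrations within the miRNA category
    w = _lognormal_weights(rng, len(mirna_genes), cfg.mirna_abundance_sigma)

    lo, hi = cfg.fold_range
    if cfg.depletion_factor == 1.0 and lo == hi == 1.0:
        rho = np.ones(len(mirna_genes))
    else:
        jitter = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(mirna_genes)))
        if len(jitter):
            jitter = jitter / np.exp(np.mean(np.log(jitter)))
        rho = cfg.depletion_factor * jitter
    truth.true_ratios = {g: float(r) for g, r in zip(mirna_genes, rho)}

    comp_wj = cfg.composition_wj
    share_wj_mirna = comp_wj.get("known_miRNA", 0.0)

    # royal-jelly miRNA share implied by the planted per-gene ratios
    if cfg.depletion_factor == 1.0 and cfg.composition_rj is not None:
        comp_rj = dict(cfg.composition_rj)
        rj_mirna_within = w.copy()
    else:
        rj_conc = share_wj_mirna * w / rho if len(w) else np.array([])
        share_rj_mirna = float(rj_conc.sum())
        base = cfg.composition_rj if cfg.composition_rj is not None else comp_wj
        rest = {c: v for c, v in base.items() if c != "known_miRNA"}
        rest_total = sum(rest.values())
        comp_rj = {"known_miRNA": share_rj_mirna}
        for c, v in rest.items():
            comp_rj[c] = (1.0 - share_rj_mirna) * (v / rest_total if rest_total else 0.0)
        rj_mirna_within = rj_conc / share_rj_mirna if share_rj_mirna > 0 else rj_conc

    # assemble per-sequence probability vectors shared between libraries
    seqs: list[str] = []
    cats: list[str] = []
    p_wj: list[float] = []
    p_rj: list[float] = []

    def add_category(category: str, within_rj: np.ndarray | None = None) -> None:
        table = catalog.sequences(category)
        if category == "known_miRNA":
            # split each gene's mass uniformly over its isoforms
            by_gene: dict[str, list[str]] = {}
            for seq, feats in table.items():
                for feat in feats:
                    by_gene.setdefault(feat, []).append(seq)
            for gi, gene in enumerate(mirna_genes):
                iso = sorted(by_gene.get(gene, []))
                for seq in iso:
                    seqs.append(seq)
                    cats.append(category)
                    p_wj.append(comp_wj.get(category, 0.0) * w[gi] / len(iso))
                    rw = within_rj[gi] if within_rj is not None and len(within_rj) else 0.0
                    p_rj.append(comp_rj.get(category, 0.0) * rw / len(iso))
                    truth.tag_features[seq] = gene
        else:
            items = sorted(table.items())
            weights = _lognormal_weights(rng, len(items), 1.0)
            for (seq, feats), wt in zip(items, weights):
                seqs.append(seq)
                cats.append(category)
                p_wj.append(comp_wj.get(category, 0.0) * wt)
                p_rj.append(comp_rj.get(category, 0.0) * wt)
                truth.tag_features[seq] = feats[0]

    add_category("known_miRNA", rj_mirna_within)
    add_category("tRNA")
    add_category("other_ncRNA")
    add_category("genic_mRNA")

    # unannotated pool: random sequences absent from the catalog
    n_unann = max(200, cfg.n_trna)
    taken = set(catalog.all_sequences()) | set(seqs)
    un_seqs = _random_seqs(rng, n_unann, rng.integers(18, 31, size=n_unann), taken)
    un_w = _lognormal_weights(rng, n_unann, 1.0)
    for seq, wt in zip(un_seqs, un_w):
        seqs.append(seq)
        cats.append("unannotated")
        p_wj.append(comp_wj.get("unannotated", 0.0) * wt)
        p_rj.append(comp_rj.get("unannotated", 0.0) * wt)
        truth.tag_features[seq] = ""

    truth.tag_categories = dict(zip(seqs, cats))

    def draw(probs: list[float], size: int, lid: str) -> TagLibrary:
        p = np.asarray(probs, dtype=float)
        if p.sum() <= 0 or size == 0:
            return TagLibrary(lid, {})
        p = p / p.sum()
        counts = rng.multinomial(size, p)
        return TagLibrary(lid, {s: int(c) for s, c in zip(seqs, counts) if c > 0})

    wj = draw(p_wj, cfg.library_size_wj, "WJ")
    rj = draw(p_rj, cfg.library_size_rj, "RJ")
    return wj, rj, truth


def gen_target_map(cfg: SimConfig, truth: GroundTruth | None = None) -> tuple[TargetMap, GroundTruth]:
    """Random miRNA->mRNA target map with planted co-targeted modules.

    Each miRNA targets a uniform-random subset of the mRNA universe (size
    drawn from ``targets_per_mirna``); on top, ``n_planted_modules``
    complete bipartite blocks (``module_mirnas`` x ``module_mrnas``) are
    planted over disjoint gene sets, giving dense co-targeting structure.
    """
    rng = cfg.rng("targets")
    truth = truth if truth is not None else GroundTruth()
    universe = mrna_universe(cfg)
    mirnas = [f"mir-{i+1:03d}" for i in range(cfg.n_mirna_genes)]
    edges: set[tuple[str, str]] = set()
    lo, hi = cfg.targets_per_mirna
    for m in mirnas:
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(universe))
        for g in rng.choice(universe, size=k, replace=False):
            edges.add((m, str(g)))
    # planted modules over the first module_mirnas*n blocks of miRNAs and
    # disjoint random gene sets
    free_genes = list(universe)
    rng.shuffle(free_genes)
    truth.planted_modules = []
    for b in range(cfg.n_planted_modules):
        ms = mirnas[b * cfg.module_mirnas:(b + 1) * cfg.module_mirnas]
        gs = free_genes[b * cfg.module_mrnas:(b + 1) * cfg.module_mrnas]
        if len(ms) < cfg.module_mirnas or len(gs) < cfg.module_mrnas:
            break
        for m in ms:
            for g in gs:
                edges.add((m, g))
        truth.planted_modules.append({"mirnas": ms, "mrnas": gs})
    tmap = TargetMap(universe=set(universe))
    for m, g in sorted(edges):
        tmap.add(m, g)
    truth.target_edges = sorted(edges)
    return tmap, truth


_DAY_EFFECTS = {
    # (day4->day5 factor range, day5->day6 factor range)
    "persistent_increase": ((1.4, 1.6), (1.05, 1.15)),
    "transient_increase": ((1.4, 4.5), (1 / 2.1, 1 / 1.7)),
    "dip": ((1 / 3.0, 1 / 1.5), (1.5, 3.0)),
    "persistent_fall": ((1 / 1.6, 1 / 1.4), (1 / 1.5, 1 / 1.3)),
    "none": ((1.0, 1.0), (1.0, 1.0)),
}


def gen_timecourse(cfg: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Three-day (day4/5/6) concentration series for both jellies.

    Worker-jelly trend classes follow ``timecourse_trends`` (remaining
    miRNAs are flat, class ``none``); every royal-jelly series is a
    drop-then-stable shape with a day4->day5 factor drawn log-uniform from
    ``rj_drop_range``.  Replicate noise is multiplicative log-normal with
    ``timecourse_noise_sd``.  Returns a long-format frame with columns
    ``mirna, jelly, day, replicate, value`` plus truth labels keyed
    ``"mirna|jelly"``.
    """
    rng = cfg.rng("timecourse")
    truth = GroundTruth()
    mirnas = [f"mir-{i+1:03d}" for i in range(cfg.n_mirna_genes)]
    wj_labels: list[str] = []
    for cls, n in cfg.timecourse_trends.items():
        wj_labels.extend([cls] * n)
    wj_labels.extend(["none"] * (cfg.n_mirna_genes - len(wj_labels)))

    rows = []
    days = (4, 5, 6)
    for mi, mirna in enumerate(mirnas):
        base_wj = float(np.exp(rng.normal(1.0, 0.5)))
        base_rj = base_wj / max(1.0, cfg.depletion_factor) * float(np.exp(rng.normal(0, 0.2)))
        # worker jelly
        cls = wj_labels[mi]
        if cls == "drop_then_stable":
            (a_lo, a_hi), (b_lo, b_hi) = (
                (1.0 / cfg.rj_drop_range[1], 1.0 / cfg.rj_drop_range[0]), (1.0, 1.0))
        else:
            (a_lo, a_hi), (b_lo, b_hi) = _DAY_EFFECTS[cls]
        f45 = float(np.exp(rng.uniform(np.log(a_lo), np.log(a_hi))))
        f56 = float(np.exp(rng.uniform(np.log(b_lo), np.log(b_hi))))
        wj_means = (base_wj, base_wj * f45, base_wj * f45 * f56)
        truth.trend_labels[f"{mirna}|WJ"] = cls
        # royal jelly: drop then stable
        dlo, dhi = cfg.rj_drop_range
        drop = float(np.exp(rng.uniform(np.log(dlo), np.log(dhi))))
        rj_means = (base_rj, base_rj / drop, base_rj / drop)
        truth.trend_labels[f"{mirna}|RJ"] = "drop_then_stable"
        for jelly, means in (("WJ", wj_means), ("RJ", rj_means)):
            for day, mu in zip(days, means):
                for rep in range(1, cfg.timecourse_replicates + 1):
                    noise = float(np.exp(rng.normal(0.0, cfg.timecourse_noise_sd))) \
                        if cfg.timecourse_noise_sd > 0 else 1.0
                    rows.append((mirna, jelly, day, rep, mu * noise))
    df = pd.DataFrame(rows, columns=["mirna", "jelly", "day", "replicate", "value"])
    return df, truth


def gen_larval_expression(
    cfg: SimConfig, target_map: TargetMap, truth: GroundTruth
) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-condition mRNA count table with planted anti-correlation.

    Targets of worker-jelly-abundant miRNAs (the first planted module's
    miRNAs, or all miRNAs when no modules are planted) are down-scaled in
    the worker condition by ``repression_factor``; all other genes are
    symmetric.  Keeping the repressed set a modest fraction of the
    transcriptome matters: counts are drawn multinomially per condition
    (``expression_depth`` reads), so only relative changes are observable
    and a widely-repressed transcriptome would compress every observed
    ratio toward 1.  Columns: ``gene, worker, queen``.
    """
    rng = cfg.rng("expression")
    universe = sorted(target_map.universe)
    base = np.exp(rng.normal(0.0, 1.0, size=len(universe)))

    if truth.planted_modules:
        high_mirnas = set(truth.planted_modules[0]["mirnas"])
    else:
        high_mirnas = set(target_map.targets)
    repressed = sorted({
        g for m in high_mirnas for g in target_map.targets.get(m, set())
    })
    truth.repressed_genes = repressed
    factor = np.ones(len(universe))
    idx = {g: i for i, g in enumerate(universe)}
    for g in repressed:
        factor[idx[g]] = cfg.repression_factor
    truth.true_mrna_ratios = {g: float(factor[idx[g]]) for g in universe}

    p_worker = base * factor
    p_queen = base.copy()
    counts_w = rng.multinomial(cfg.expression_depth, p_worker / p_worker.sum()) \
        if cfg.expression_depth > 0 else np.zeros(len(universe), dtype=int)
    counts_q = rng.multinomial(cfg.expression_depth, p_queen / p_queen.sum()) \
        if cfg.expression_depth > 0 else np.zeros(len(universe), dtype=int)
    df = pd.DataFrame({"gene": universe, "worker": counts_w, "queen": counts_q})
    return df, truth


def gen_morpho(cfg: SimConfig) -> tuple[pd.DataFrame, list, GroundTruth]:
    """Per-bee morphometric table for the feeding experiment.

    Groups: untreated, control (solvent only) and treated (miRNA in food).
    Traits are normal with control means/SDs from ``morpho_control``; the
    treated group's mean is shifted multiplicatively by ``morpho_effects``
    (e.g. -0.08 = 8% lighter).  Returns the raw table, its per-group/trait
    summaries and the truth (true group means).
    """
    from jellynet.morpho import MorphoSummary, summarize_morpho

    rng = cfg.rng("morpho")
    truth = GroundTruth()
    rows = []
    bee = 0
    for group in ("untreated", "control", "treated"):
        n = cfg.group_ns[group]
        truth.trait_means[group] = {}
        for _ in range(n):
            bee += 1
            row: dict[str, object] = {"bee_id": f"bee-{bee:04d}", "group": group}
            for trait, (mean, sd) in cfg.morpho_control.items():
                mu = mean
                if group == "treated":
                    mu = mean * (1.0 + cfg.morpho_effects.get(trait, 0.0))
                truth.trait_means[group][trait] = mu
                row[trait] = float(rng.normal(mu, sd))
            rows.append(row)
    df = pd.DataFrame(rows)
    summaries = summarize_morpho(df)
    return df, summaries, truth


def gen_term_sets(cfg: SimConfig, truth: GroundTruth, n_random_terms: int = 20
                  ) -> dict[str, set[str]]:
    """Synthetic GMT-style term sets: one term per planted module's genes
    plus random decoy terms over the mRNA universe."""
    rng = cfg.rng("terms")
    universe = mrna_universe(cfg)
    terms: dict[str, set[str]] = {}
    for i, mod in enumerate(truth.planted_modules):
        terms[f"planted_module_{i+1}"] = set(mod["mrnas"])
    for i in range(n_random_terms):
        k = int(rng.integers(10, 60))
        terms[f"random_term_{i+1:02d}"] = {
            str(g) for g in rng.choice(universe, size=k, replace=False)}
    return terms
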