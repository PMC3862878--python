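"""End-to-end pipeline driver: replay the whole study on synthetic data.

Stages run in study order -- simulate, profile, diff, network, modules,
enrich, timecourse, morpho -- each writing its artifacts under the output
directory and contributing to a machine-readable run report that embeds
the fully resolved configuration and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from jellynet import counts, enrichment, morpho, network, profiling, simulate, timecourse

logger = logging.getLogger("jellynet")

STAGES = ("simulate", "profile", "diff", "network", "modules", "enrich",
          "timecourse", "morpho")

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "STAGES"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration.

    Thresholds: ``fold_thresh``/``p_thresh`` gate both the DE rule and the
    network's concordant-pair rule; ``alpha`` is the trend-call level;
    ``detection_min`` the presence threshold; ``vwp`` the MCODE vertex
    weight percentage; ``seed_span`` the miRNA seed positions.
    """

    seed: int = 0
    outdir: str = "jellynet_run"
    stages: tuple[str, ...] = STAGES
    fold_thresh: float = 2.0
    p_thresh: float = 0.01
    alpha: float = 0.01
    detection_min: int = 1
    vwp: float = 0.2
    seed_span: tuple[int, int] = (2, 8)
    pseudocount: float = 0.5
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    _FIELDS = ("seed", "outdir", "stages", "fold_thresh", "p_thresh", "alpha",
               "detection_min", "vwp", "seed_span", "pseudocount", "sim")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fold_thresh < 1:
            raise ValueError("fold_thresh must be >= 1")
        if not (0 < self.p_thresh <= 1):
            raise ValueError("p_thresh must lie in (0, 1]")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0 <= self.vwp < 1):
            raise ValueError("vwp must lie in [0, 1)")
        if self.detection_min < 0:
            raise ValueError("detection_min must be >= 0")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls._FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in d:
            d = {**d, "stages": tuple(d["stages"])}
        if "seed_span" in d:
            d = {**d, "seed_span": tuple(d["seed_span"])}
        return cls(**d)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages and return (and write) the run report.

    Any stage failure raises :class:`StageError` naming the stage; artifacts
    from completed stages remain on disk.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": {**{k: getattr(cfg, k) for k in cfg._FIELDS if k != "sim"},
                   "sim": dict(cfg.sim)},
        "seed": cfg.seed,
        "stages": {},
    }
    state: dict = {}

    def stage(name):
        def deco(fn):
            if name in cfg.stages:
                t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                try:
                    report["stages"][name] = fn()
                except Exception as exc:  # noqa: BLE001 - abort with stage name
                    _write_report(report, outdir)
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return fn
        return deco

    @stage("simulate")
    def _simulate():
        sim_cfg = simulate.SimConfig(seed=cfg.seed, **cfg.sim)
        state["sim_cfg"] = sim_cfg
        catalog = simulate.gen_annotation(sim_cfg)
        wj, rj, truth = simulate.gen_jelly_libraries(sim_cfg, catalog)
        tmap, truth = simulate.gen_target_map(sim_cfg, truth)
        expr, truth = simulate.gen_larval_expression(sim_cfg, tmap, truth)
        tc, tc_truth = simulate.gen_timecourse(sim_cfg)
        truth.trend_labels = tc_truth.trend_labels
        raw_morpho, summaries, m_truth = simulate.gen_morpho(sim_cfg)
        truth.trait_means = m_truth.trait_means
        terms = simulate.gen_term_sets(sim_cfg, truth)
        state.update(catalog=catalog, wj=wj, rj=rj, truth=truth, tmap=tmap,
                     expr=expr, tc_data=tc, raw_morpho=raw_morpho,
                     morpho_summaries=summaries, terms=terms)
        catalog.to_fasta(outdir / "catalog.fa")
        wj.to_tsv(outdir / "wj_tags.tsv")
        rj.to_tsv(outdir / "rj_tags.tsv")
        tmap.to_tsv(outdir / "target_map.tsv")
        expr.to_csv(outdir / "larval_expression.tsv", sep="\t", index=False,
                    lineterminator="\n")
        tc.to_csv(outdir / "timecourse.tsv", sep="\t", index=False,
                  lineterminator="\n")
        raw_morpho.to_csv(outdir / "morpho.csv", index=False, lineterminator="\n")
        enrichment.write_gmt(terms, outdir / "terms.gmt")
        truth.to_json(outdir / "truth.json")
        return {"wj_reads": wj.total_reads, "rj_reads": rj.total_reads,
                "n_mirna_genes": sim_cfg.n_mirna_genes,
                "target_edges": tmap.n_edges}

    @stage("profile")
    def _profile():
        out = {}
        profiles = []
        for key in ("wj", "rj"):
            lib = profiling.filter_tags(state[key])
            classified = profiling.classify_tags(lib, state["catalog"])
            classified.to_tsv(outdir / f"{key}_classified.tsv")
            comp = profiling.composition(classified)
            prof = profiling.quantify_mirnas(
                classified, genes=state["catalog"].features("known_miRNA"))
            prof.to_tsv(outdir / f"{key}_profile.tsv")
            profiles.append(prof)
            out[key] = {"composition": comp, "total_reads": lib.total_reads}
        state["profiles"] = profiles
        det = profiling.detection_summary(profiles, cfg.detection_min)
        state["detection"] = det
        out["detected"] = det["n_detected"]
        out["n_low_count"] = len(det["low_count"])
        return out

    @stage("diff")
    def _diff():
        wj_prof, rj_prof = state["profiles"]
        n1 = max(wj_prof.library_size, 1)
        n2 = max(rj_prof.library_size, 1)
        pairs = [
            counts.CountPair(g, wj_prof.counts.get(g, 0), rj_prof.counts.get(g, 0), n1, n2)
            for g in sorted(set(wj_prof.counts) | set(rj_prof.counts))
        ]
        mirna_diff = counts.diff_table(pairs, cfg.pseudocount)
        mirna_diff.to_csv(outdir / "mirna_diff.tsv", sep="\t", lineterminator="\n")
        state["mirna_diff"] = mirna_diff
        expr = state["expr"]
        nw, nq = max(int(expr["worker"].sum()), 1), max(int(expr["queen"].sum()), 1)
        mrna_pairs = [
            counts.CountPair(g, int(w), int(q), nw, nq)
            for g, w, q in zip(expr["gene"], expr["worker"], expr["queen"])
        ]
        mrna_diff = counts.diff_table(mrna_pairs, cfg.pseudocount)
        mrna_diff.to_csv(outdir / "mrna_diff.tsv", sep="\t", lineterminator="\n")
        state["mrna_diff"] = mrna_diff
        de = counts.de_genes(mrna_pairs, cfg.fold_thresh, cfg.p_thresh, cfg.pseudocount)
        state["de"] = de
        sig = mirna_diff[(mirna_diff["p"] < cfg.p_thresh)
                         & (mirna_diff["direction"] == "up_in_1")]
        return {"n_mirna_up_in_wj": int(len(sig)), "n_de_mrna": de["n_de"],
                "n_de_down_in_worker": len(de["down"])}

    @stage("network")
    def _network():
        edges = network.select_concordant_pairs(
            state["mirna_diff"], state["mrna_diff"], state["tmap"],
            cfg.fold_thresh, cfg.p_thresh)
        net = network.build_network(edges)
        state["net"] = net
        with open(outdir / "network_edges.tsv", "w", encoding="utf-8",
                  newline="\n") as fh:
            for m, g, s in edges:
                fh.write(f"{m}\t{g}\t{s}\n")
        return {"node_count": net.node_count, "edge_count": net.edge_count}

    @stage("modules")
    def _modules():
        mods = network.mcode_modules(state["net"], vwp=cfg.vwp)
        state["modules"] = mods
        rows = [(i + 1, str(v), mod.weights[v])
                for i, mod in enumerate(mods) for v in sorted(mod.vertices, key=str)]
        pd.DataFrame(rows, columns=["module", "vertex", "weight"]).to_csv(
            outdir / "modules.tsv", sep="\t", index=False, lineterminator="\n")
        return {"n_modules": len(mods),
                "scores": [round(m.score, 4) for m in mods[:10]]}

    @stage("enrich")
    def _enrich():
        universe = sorted(state["tmap"].universe)
        out = []
        all_results = []
        for i, mod in enumerate(state.get("modules", [])[:4]):
            genes = {v for v in mod.vertices if v in state["tmap"].universe}
            if not genes:
                continue
            res = enrichment.enrich(genes, state["terms"], universe)
            all_results.extend(res)
            top = res[0]
            out.append({"module": i + 1, "top_term": top.term,
                        "p": top.p, "q": top.q})
        if all_results:
            enrichment.results_frame(all_results).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False,
                lineterminator="\n")
        return {"modules": out}

    @stage("timecourse")
    def _timecourse():
        tc = timecourse.TimeCourse(state["tc_data"], scale="raw")
        rel = timecourse.scale_to_reference(tc)
        calls = timecourse.classify_trends(rel, alpha=cfg.alpha)
        pd.DataFrame([c.__dict__ for c in calls]).to_csv(
            outdir / "trend_calls.tsv", sep="\t", index=False, lineterminator="\n")
        state["trend_calls"] = calls
        counts_by_class: dict[str, int] = {}
        for c in calls:
            counts_by_class[c.trend] = counts_by_class.get(c.trend, 0) + 1
        truth = state["truth"].trend_labels
        correct = sum(1 for c in calls if truth.get(f"{c.mirna}|{c.jelly}") == c.trend)
        return {"class_counts": counts_by_class,
                "accuracy_vs_planted": correct / len(calls) if calls else None}

    @stage("morpho")
    def _morpho():
        raw = state["raw_morpho"]
        traits = [c for c in raw.columns if c not in ("bee_id", "group")]
        groups = ["untreated", "control", "treated"]
        out = {}
        for trait in traits:
            samples = [raw[raw["group"] == g][trait].to_numpy() for g in groups]
            an = morpho.anova_oneway(samples, groups)
            tk = morpho.tukey_hsd(samples, groups)
            ct = next(t for t in tk if set(t.groups) == {"control", "treated"})
            out[trait] = {"F": an.statistic, "anova_p": an.p,
                          "tukey_control_vs_treated_p": ct.p}
        summaries = {(s.group, s.trait): s for s in state["morpho_summaries"]}
        for trait in traits:
            tt = morpho.ttest_from_summary(
                summaries[("control", trait)], summaries[("treated", trait)])
            eff = morpho.percent_effect(
                summaries[("treated", trait)], summaries[("control", trait)])
            out[trait]["ttest_p"] = tt.p
            out[trait]["percent_effect"] = eff
        return out

    _write_report(report, outdir)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, tuple)):
        return sorted(o) if isinstance(o, set) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "report.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
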