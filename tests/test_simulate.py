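"""Synthetic-data generator: determinism, planted structure, recovery."""

import numpy as np
import pandas as pd
import pytest

from jellynet import (
    SimConfig, gen_annotation, gen_jelly_libraries, gen_larval_expression,
    gen_morpho, gen_target_map, gen_timecourse, gen_utrs,
)
from jellynet.simulate import _random_seqs, mrna_universe


def _cfg(**kw) -> SimConfig:
    base = dict(seed=1, n_mirna_genes=20, n_trna=20, n_other_nc=10,
                n_mrna=100, library_size_wj=20_000, library_size_rj=20_000,
                targets_per_mirna=(5, 15), expression_depth=100_000,
                timecourse_trends={"persistent_increase": 5, "dip": 5})
    base.update(kw)
    return SimConfig(**base)


class TestAnnotation:
    def test_identical_seeds_identical_catalogs(self):
        a = gen_annotation(_cfg())
        b = gen_annotation(_cfg())
        for cat in ("known_miRNA", "tRNA", "other_ncRNA", "genic_mRNA"):
            assert a.sequences(cat) == b.sequences(cat)

    def test_different_seeds_differ(self):
        a = gen_annotation(_cfg(seed=1))
        b = gen_annotation(_cfg(seed=2))
        assert a.sequences("known_miRNA") != b.sequences("known_miRNA")

    def test_empty_mirna_class(self):
        cat = gen_annotation(_cfg(n_mirna_genes=0, timecourse_trends={}))
        assert cat.sequences("known_miRNA") == {}
        assert len(cat.sequences("tRNA")) == 20

    def test_sequences_unique_across_categories(self, small_catalog):
        seqs = []
        for cat in ("known_miRNA", "tRNA", "other_ncRNA", "genic_mRNA"):
            seqs.extend(small_catalog.sequences(cat))
        assert len(seqs) == len(set(seqs))

    def test_every_gene_has_an_isoform(self, small_cfg, small_catalog):
        assert len(small_catalog.features("known_miRNA")) == small_cfg.n_mirna_genes

    def test_kmer_space_exhaustion_fails_loudly(self, rng):
        with pytest.raises(ValueError, match="k-mer space"):
            _random_seqs(rng, 5, np.array([1]), set())


class TestJellyLibraries:
    def test_composition_recovered_within_binomial_margin(self):
        cfg = _cfg(library_size_wj=200_000)
        cat = gen_annotation(cfg)
        wj, _, truth = gen_jelly_libraries(cfg, cat)
        mirna_reads = sum(c for s, c in wj.tags.items()
                          if truth.tag_categories[s] == "known_miRNA")
        frac = mirna_reads / wj.total_reads
        assert frac == pytest.approx(0.51, abs=0.02)

    def test_null_configuration_all_ratios_one(self):
        cfg = _cfg(depletion_factor=1.0, fold_range=(1.0, 1.0),
                   composition_rj=None)
        cat = gen_annotation(cfg)
        _, _, truth = gen_jelly_libraries(cfg, cat)
        assert set(truth.true_ratios.values()) == {1.0}

    def test_fixed_seed_byte_identical_tsv(self, tmp_path):
        for run in ("a", "b"):
            cfg = _cfg()
            cat = gen_annotation(cfg)
            wj, _, _ = gen_jelly_libraries(cfg, cat)
            wj.to_tsv(tmp_path / f"{run}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_zero_library_size_gives_empty_valid_library(self):
        cfg = _cfg(library_size_wj=0)
        cat = gen_annotation(cfg)
        wj, rj, _ = gen_jelly_libraries(cfg, cat)
        assert wj.tags == {} and wj.total_reads == 0
        assert rj.total_reads > 0

    def test_true_ratio_geometric_mean_equals_depletion(self):
        cfg = _cfg(depletion_factor=20.0, fold_range=(7.0, 215.0))
        cat = gen_annotation(cfg)
        _, _, truth = gen_jelly_libraries(cfg, cat)
        ratios = np.array(list(truth.true_ratios.values()))
        assert np.exp(np.mean(np.log(ratios))) == pytest.approx(20.0, rel=1e-9)

    def test_category_labels_match_composition_chi2(self):
        # label frequencies converge to the composition vector
        from scipy.stats import chisquare
        cfg = _cfg(library_size_wj=100_000)
        cat = gen_annotation(cfg)
        wj, _, truth = gen_jelly_libraries(cfg, cat)
        observed = {}
        for s, c in wj.tags.items():
            observed[truth.tag_categories[s]] = observed.get(
                truth.tag_categories[s], 0) + c
        cats = [c for c, p in cfg.composition_wj.items() if p > 0]
        obs = np.array([observed.get(c, 0) for c in cats], dtype=float)
        exp = np.array([cfg.composition_wj[c] for c in cats]) * obs.sum()
        assert chisquare(obs, exp).pvalue > 0.001


class TestTimecourse:
    def test_noiseless_persistent_fall_monotone(self):
        cfg = _cfg(timecourse_noise_sd=0.0,
                   timecourse_trends={"persistent_fall": 20})
        df, truth = gen_timecourse(cfg)
        for mirna in df["mirna"].unique():
            sub = df[(df["mirna"] == mirna) & (df["jelly"] == "WJ")]
            m = sub.groupby("day")["value"].mean()
            assert m[4] > m[5] > m[6]

    def test_planted_drop_factor_exact_at_zero_noise(self):
        cfg = _cfg(timecourse_noise_sd=0.0, rj_drop_range=(2.6, 2.6))
        df, _ = gen_timecourse(cfg)
        sub = df[df["jelly"] == "RJ"]
        m = sub.groupby(["mirna", "day"])["value"].mean().unstack()
        assert np.allclose(m[4] / m[5], 2.6)
        assert np.allclose(m[5], m[6])

    def test_fixed_seed_identical_matrices(self):
        a, _ = gen_timecourse(_cfg())
        b, _ = gen_timecourse(_cfg())
        pd.testing.assert_frame_equal(a, b)

    def test_trend_counts_validated(self):
        with pytest.raises(ValueError, match="trend counts"):
            _cfg(timecourse_trends={"dip": 50})


class TestLarvalExpression:
    def test_unit_repression_all_ratios_one(self):
        cfg = _cfg(repression_factor=1.0)
        tmap, truth = gen_target_map(cfg)
        _, truth = gen_larval_expression(cfg, tmap, truth)
        assert set(truth.true_mrna_ratios.values()) == {1.0}

    def test_planted_targets_get_configured_ratio(self):
        from jellynet import TargetMap
        cfg = _cfg(repression_factor=0.5, n_planted_modules=0)
        universe = mrna_universe(cfg)
        tmap = TargetMap(universe=set(universe))
        for g in universe[:10]:
            tmap.add("mir-001", g)
        from jellynet.simulate import GroundTruth
        _, truth = gen_larval_expression(cfg, tmap, GroundTruth())
        assert all(truth.true_mrna_ratios[g] == 0.5 for g in universe[:10])
        assert all(truth.true_mrna_ratios[g] == 1.0 for g in universe[10:])

    def test_fixed_seed_reproducible(self):
        cfg = _cfg()
        tmap, truth = gen_target_map(cfg)
        a, _ = gen_larval_expression(cfg, tmap, truth)
        b, _ = gen_larval_expression(cfg, tmap, truth)
        pd.testing.assert_frame_equal(a, b)


class TestTargetMap:
    def test_planted_modules_are_complete_blocks(self):
        cfg = _cfg(n_mrna=200, n_planted_modules=2)
        tmap, truth = gen_target_map(cfg)
        assert len(truth.planted_modules) == 2
        for mod in truth.planted_modules:
            for m in mod["mirnas"]:
                assert set(mod["mrnas"]) <= tmap.targets[m]

    def test_planted_genes_within_universe(self):
        cfg = _cfg()
        tmap, truth = gen_target_map(cfg)
        for mod in truth.planted_modules:
            assert set(mod["mrnas"]) <= tmap.universe


class TestMorpho:
    def test_zero_effects_equal_true_means(self):
        cfg = _cfg(morpho_effects={})
        _, _, truth = gen_morpho(cfg)
        for trait in cfg.morpho_control:
            means = {truth.trait_means[g][trait] for g in truth.trait_means}
            assert len(means) == 1

    def test_treated_mean_within_clt_bound(self):
        cfg = _cfg(group_ns={"untreated": 2, "control": 2, "treated": 10_000},
                   morpho_effects={"birth_weight": -0.08},
                   morpho_control={"birth_weight": (0.2355, 0.02)})
        df, _, _ = gen_morpho(cfg)
        treated = df[df["group"] == "treated"]["birth_weight"]
        se = 0.02 / np.sqrt(10_000)
        assert abs(treated.mean() - 0.2355 * 0.92) < 4 * se

    def test_summary_matches_raw_table(self):
        cfg = _cfg()
        df, summaries, _ = gen_morpho(cfg)
        for s in summaries:
            col = df[df["group"] == s.group][s.trait]
            assert s.mean == pytest.approx(col.mean())
            assert s.sd == pytest.approx(col.std(ddof=1))
            assert s.n == len(col)


def test_end_to_end_depletion_recovery():
    """Full profiling+testing chain on generated libraries recovers the
    planted global depletion within 30%."""
    from jellynet import CountPair, classify_tags, diff_table, filter_tags, quantify_mirnas
    cfg = SimConfig(seed=5, n_mirna_genes=200, n_trna=100, n_other_nc=50,
                    n_mrna=500, library_size_wj=200_000, library_size_rj=200_000,
                    depletion_factor=20.0, timecourse_trends={},
                    targets_per_mirna=(10, 30))
    cat = gen_annotation(cfg)
    wj, rj, truth = gen_jelly_libraries(cfg, cat)
    genes = cat.features("known_miRNA")
    pw = quantify_mirnas(classify_tags(filter_tags(wj), cat), genes)
    pr = quantify_mirnas(classify_tags(filter_tags(rj), cat), genes)
    pairs = [CountPair(g, pw.counts[g], pr.counts[g], wj.total_reads, rj.total_reads)
             for g in sorted(genes)]
    table = diff_table(pairs)
    informative = table[table["x"] >= 100]
    med = float(np.median(informative["fold_change"]))
    assert med == pytest.approx(20.0, rel=0.30)


def test_utrs_cover_universe(small_cfg):
    utrs = gen_utrs(small_cfg)
    assert set(utrs) == set(mrna_universe(small_cfg))
    assert all(len(u) == small_cfg.utr_length for u in utrs.values())
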