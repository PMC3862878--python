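"""Target prediction, concordant-pair network, MCODE modules and the
co-targeting statistic."""

from itertools import product

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from jellynet import (
    TargetMap, build_network, cotarget_stat, mcode_modules,
    mcode_vertex_weights, seed_match_targets, select_concordant_pairs,
)
from jellynet.network import _revcomp, poisson_binomial_tail


class TestSeedMatch:
    def test_matches_bruteforce_scan(self, rng):
        mirnas = {f"m{i}": "".join(rng.choice(list("ACGT"), size=22))
                  for i in range(10)}
        utrs = {f"g{i}": "".join(rng.choice(list("ACGT"), size=300))
                for i in range(30)}
        tmap = seed_match_targets(mirnas, utrs)
        for m, g in product(mirnas, utrs):
            site = _revcomp(mirnas[m][1:8])
            hit = any(utrs[g][i:i + 7] == site
                      for i in range(len(utrs[g]) - 6))
            assert (g in tmap.targets[m]) == hit

    def test_gc_seed_cannot_match_polya_utr(self):
        tmap = seed_match_targets({"m": "TTAGGCACCTTTTTTTTTTT"}, {"g": "A" * 100})
        assert tmap.targets["m"] == set()

    def test_empty_utr_set(self):
        tmap = seed_match_targets({"m": "ACGTACGTACGTACGTACGT"}, {})
        assert tmap.universe == set()
        assert tmap.targets["m"] == set()

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="shorter than seed"):
            seed_match_targets({"m": "ACGTA"}, {"g": "ACGT" * 30})

    def test_u_to_t_normalization(self):
        # RNA-alphabet miRNA whose DNA seed complement is planted in the UTR
        mirna = "UUAGGCACCU" + "U" * 10
        site = _revcomp("TAGGCAC")
        tmap = seed_match_targets({"m": mirna}, {"g": "C" * 20 + site + "C" * 20})
        assert tmap.targets["m"] == {"g"}


def _diff_frame(rows):
    return pd.DataFrame(
        rows, columns=["feature", "fold_change", "p"]).set_index("feature")


class TestConcordantPairs:
    def test_rule_keeps_anticorrelated_pair(self):
        mi = _diff_frame([("m1", 10.0, 1e-4)])
        mr = _diff_frame([("g1", 0.4, 1e-3)])
        tmap = TargetMap(universe={"g1"}, targets={"m1": {"g1"}})
        assert select_concordant_pairs(mi, mr, tmap) == [("m1", "g1", +1)]

    def test_discordant_pair_dropped(self):
        mi = _diff_frame([("m1", 10.0, 1e-4)])
        mr = _diff_frame([("g1", 3.0, 1e-3)])  # target UP in worker
        tmap = TargetMap(universe={"g1"}, targets={"m1": {"g1"}})
        assert select_concordant_pairs(mi, mr, tmap) == []

    def test_fixture_matches_independent_rule_evaluation(self, rng):
        genes = [f"g{i}" for i in range(20)]
        mirnas = [f"m{i}" for i in range(5)]
        mi_rows = [(m, float(np.exp(rng.normal(0, 2))), float(rng.uniform(0, 0.05)))
                   for m in mirnas]
        mr_rows = [(g, float(np.exp(rng.normal(0, 2))), float(rng.uniform(0, 0.05)))
                   for g in genes]
        tmap = TargetMap(universe=set(genes))
        for m in mirnas:
            for g in rng.choice(genes, size=8, replace=False):
                tmap.add(m, str(g))
        kept = select_concordant_pairs(
            _diff_frame(mi_rows), _diff_frame(mr_rows), tmap)
        mi_map = {m: (f, p) for m, f, p in mi_rows}
        mr_map = {g: (f, p) for g, f, p in mr_rows}
        expected = []
        for m in sorted(tmap.targets):
            fm, pm = mi_map[m]
            for g in sorted(tmap.targets[m]):
                fg, pg = mr_map[g]
                m_up = fm >= 2 and pm < 0.01
                m_dn = fm <= 0.5 and pm < 0.01
                g_up = fg >= 2 and pg < 0.01
                g_dn = fg <= 0.5 and pg < 0.01
                if m_up and g_dn:
                    expected.append((m, g, +1))
                elif m_dn and g_up:
                    expected.append((m, g, -1))
        assert kept == expected

    def test_direction_reversal_flips_signs_only(self):
        mi = _diff_frame([("m1", 10.0, 1e-4), ("m2", 0.1, 1e-4)])
        mr = _diff_frame([("g1", 0.3, 1e-3), ("g2", 4.0, 1e-3)])
        tmap = TargetMap(universe={"g1", "g2"},
                         targets={"m1": {"g1", "g2"}, "m2": {"g1", "g2"}})
        kept = select_concordant_pairs(mi, mr, tmap)
        mi_rev = _diff_frame([("m1", 0.1, 1e-4), ("m2", 10.0, 1e-4)])
        mr_rev = _diff_frame([("g1", 1 / 0.3, 1e-3), ("g2", 0.25, 1e-3)])
        kept_rev = select_concordant_pairs(mi_rev, mr_rev, tmap)
        assert {(m, g) for m, g, _ in kept} == {(m, g) for m, g, _ in kept_rev}
        signs = {(m, g): s for m, g, s in kept}
        signs_rev = {(m, g): s for m, g, s in kept_rev}
        assert all(signs[k] == -signs_rev[k] for k in signs)


class TestBuildNetwork:
    def test_star_counts(self):
        net = build_network([("m1", "g1", 1), ("m1", "g2", 1), ("m1", "g3", 1)])
        assert net.node_count == 4
        assert net.edge_count == 3

    def test_duplicate_edges_counted_once(self):
        net = build_network([("m1", "g1", 1), ("m1", "g1", 1)])
        assert net.edge_count == 1

    def test_bipartition_violation_rejected(self):
        with pytest.raises(ValueError, match="both sides"):
            build_network([("m1", "g1", 1), ("g1", "m2", 1)])

    def test_random_fixture_vs_naive_counting(self, rng):
        edges = {(f"m{rng.integers(5)}", f"g{rng.integers(20)}") for _ in range(60)}
        net = build_network([(m, g, 1) for m, g in edges])
        nodes = {m for m, _ in edges} | {g for _, g in edges}
        assert net.edge_count == len(edges)
        assert net.node_count == len(nodes)


class TestMCODE:
    def test_edgeless_graph_no_modules(self):
        g = nx.empty_graph(5)
        assert mcode_modules(g) == []

    def test_k4_weights_and_single_module(self):
        g = nx.complete_graph(4)
        weights = mcode_vertex_weights(g)
        assert all(w == pytest.approx(3.0) for w in weights.values())
        mods = mcode_modules(g)
        assert len(mods) == 1
        assert mods[0].vertices == set(g.nodes)
        assert mods[0].score == pytest.approx(4.0)  # density 1 x size 4

    @staticmethod
    def planted_bipartite(seed: int):
        """100-node random bipartite background (p=0.02) with a planted
        complete K5,5 block (block edges define the planted vertices)."""
        rng = np.random.default_rng(seed)
        a = [f"a{i:02d}" for i in range(50)]
        b = [f"b{i:02d}" for i in range(50)]
        g = nx.Graph()
        g.add_nodes_from(a)
        g.add_nodes_from(b)
        planted = set(a[:5]) | set(b[:5])
        for u in a:
            for v in b:
                if u in planted or v in planted:
                    continue
                if rng.random() < 0.02:
                    g.add_edge(u, v)
        for u in a[:5]:
            for v in b[:5]:
                g.add_edge(u, v)
        return g, planted

    def test_planted_block_recovered_as_top_module(self):
        g, planted = self.planted_bipartite(seed=2024)
        mods = mcode_modules(g)
        assert len(mods[0].vertices & planted) >= 9

    def test_weights_bounded_and_core_level_monotone(self, rng):
        # weight = k * density(core) is bounded by the max degree; the core
        # level k itself never increases when an edge is removed.  (The
        # weight product is NOT monotone: a shrinking core can get denser.)
        g = nx.gnp_random_graph(30, 0.15, seed=7)

        def core_levels(graph):
            out = {}
            for v in graph:
                sub = graph.subgraph(list(graph.neighbors(v)) + [v])
                out[v] = max(nx.core_number(sub).values())
            return out

        w = mcode_vertex_weights(g)
        max_deg = max(dict(g.degree).values())
        assert all(0 <= x <= max_deg for x in w.values())
        levels = core_levels(g)
        g2 = g.copy()
        edges = list(g2.edges)
        g2.remove_edge(*edges[rng.integers(len(edges))])
        levels2 = core_levels(g2)
        assert all(levels2[v] <= levels[v] for v in g2.nodes)

    def test_determinism(self):
        g, _ = self.planted_bipartite(seed=3)
        a = mcode_modules(g)
        b = mcode_modules(g)
        assert [m.vertices for m in a] == [m.vertices for m in b]
        assert [m.seed for m in a] == [m.seed for m in b]

    def test_haircut_removes_pendant_vertices(self):
        g = nx.complete_graph(4)
        g.add_edge(0, "pendant")
        mods = mcode_modules(g, haircut=True)
        assert "pendant" not in mods[0].vertices


class TestCotarget:
    def _map(self):
        tmap = TargetMap(universe={f"g{i}" for i in range(4)})
        tmap.targets = {"m1": {"g0", "g1"}, "m2": {"g2", "g3"}}
        return tmap

    def test_k_zero_certain(self):
        st = cotarget_stat(self._map(), ["m1", "m2"], 0, 0)
        assert st.p_single == 1.0

    def test_two_coin_case_and_poisson_tail(self):
        st = cotarget_stat(self._map(), ["m1", "m2"], 2, 1)
        assert st.p_single == pytest.approx(0.25)
        assert st.expected_cases == pytest.approx(1.0)
        assert st.p_multi == pytest.approx(1 - np.exp(-1), rel=1e-12)

    def test_equal_probability_reduces_to_binomial(self):
        from scipy import stats as ss
        assert poisson_binomial_tail([0.1] * 10, 6) == pytest.approx(
            float(ss.binom.sf(5, 10, 0.1)), abs=1e-14)

    @pytest.mark.parametrize("m", [5, 9, 12])
    def test_dp_matches_exhaustive_enumeration(self, m, rng):
        probs = rng.uniform(0.05, 0.6, size=m)
        for k in (0, 1, m // 2, m):
            total = 0.0
            for mask in range(2**m):
                hits = bin(mask).count("1")
                if hits < k:
                    continue
                pr = 1.0
                for i in range(m):
                    pr *= probs[i] if (mask >> i) & 1 else 1 - probs[i]
                total += pr
            assert poisson_binomial_tail(probs, k) == pytest.approx(
                total, abs=1e-12)

    def test_k_exceeding_m_rejected(self):
        with pytest.raises(ValueError):
            cotarget_stat(self._map(), ["m1", "m2"], 3, 1)

    def test_unknown_mirna_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            cotarget_stat(self._map(), ["m1", "mX"], 1, 1)


def test_concordant_edges_subset_of_target_map(rng):
    genes = [f"g{i}" for i in range(15)]
    tmap = TargetMap(universe=set(genes))
    for m in ("m1", "m2"):
        for g in rng.choice(genes, size=6, replace=False):
            tmap.add(m, str(g))
    mi = _diff_frame([("m1", 8.0, 1e-5), ("m2", 0.1, 1e-5)])
    mr = _diff_frame([(g, float(np.exp(rng.normal(0, 2))), 1e-4) for g in genes])
    kept = select_concordant_pairs(mi, mr, tmap)
    for m, g, _ in kept:
        assert g in tmap.targets[m]


def test_target_map_tsv_roundtrip(tmp_path):
    tmap = TargetMap(universe={"g1", "g2", "g3"})
    tmap.add("m1", "g1")
    tmap.add("m1", "g3")
    tmap.add("m2", "g2")
    path = tmp_path / "map.tsv"
    tmap.to_tsv(path)
    back = TargetMap.from_tsv(path, universe=tmap.universe)
    assert back.targets == tmap.targets
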