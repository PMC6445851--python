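"""First-order networks, hypergeometric enrichment, BH FDR, empirical P."""

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from targetgene import simulate
from targetgene.network import (
    NetworkEnrichment,
    PathwayDB,
    bh_fdr,
    empirical_pathway_pvalues,
    first_order_network,
    hypergeom_enrich,
    read_gmt,
    write_gmt,
)


def star(n_leaves=5):
    g = nx.star_graph(n_leaves)
    return nx.relabel_nodes(
        g, {0: "c", **{i: f"l{i}" for i in range(1, n_leaves + 1)}}
    )


class TestFirstOrderNetwork:
    def test_center_seed_covers_whole_star(self):
        sub, roles, missing = first_order_network(star(), {"c"})
        assert set(sub.nodes) == {"c", "l1", "l2", "l3", "l4", "l5"}
        assert roles["c"] == "seed" and roles["l1"] == "interactor"
        assert missing == []

    def test_leaf_seed_reaches_only_center(self):
        sub, _, _ = first_order_network(star(), {"l1"})
        assert set(sub.nodes) == {"l1", "c"}
        assert sub.number_of_edges() == 1

    def test_missing_seed_reported_not_dropped(self):
        sub, _, missing = first_order_network(star(), {"zzz"})
        assert sub.number_of_nodes() == 0
        assert missing == ["zzz"]

    def test_isolated_present_seed_retained(self):
        g = star()
        g.add_node("iso")
        sub, roles, _ = first_order_network(g, {"iso"})
        assert set(sub.nodes) == {"iso"}

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            first_order_network(star(), set())

    def test_matches_bruteforce_adjacency_scan(self, rng):
        for _ in range(200):
            g = nx.gnp_random_graph(
                25, 0.12, seed=int(rng.integers(0, 2**31))
            )
            seeds = set(
                int(x) for x in rng.choice(25, size=3, replace=False)
            )
            sub, _, _ = first_order_network(g, seeds)
            expected_nodes = {
                s for s in seeds if s in g
            } | {
                v for s in seeds if s in g for v in g.neighbors(s)
            }
            assert set(sub.nodes) == expected_nodes
            expected_edges = {
                frozenset(e)
                for e in g.edges
                if e[0] in expected_nodes and e[1] in expected_nodes
            }
            assert {frozenset(e) for e in sub.edges} == expected_edges


def hypergeom_tail_fraction(n_universe, total, draws, hits):
    """Exact upper tail by integer combinatorics (Fraction arithmetic)."""
    num = sum(
        math.comb(total, j) * math.comb(n_universe - total, draws - j)
        for j in range(hits, min(total, draws) + 1)
    )
    return Fraction(num, math.comb(n_universe, draws))


class TestHypergeomEnrich:
    def test_zero_hits_gives_p_one(self):
        db = PathwayDB({"pw": {"a", "b"}})
        out = hypergeom_enrich({"x"}, db, universe={"a", "b", "x", "y"})
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert out.loc[0, "hits"] == 0

    def test_frozen_exhaustive_example(self):
        """|U|=20, draws=5, Total=4, Hits=2 -> 3856/15504 ~ 0.24871."""
        universe = {f"u{i}" for i in range(20)}
        pw = {f"u{i}" for i in range(4)}
        net = {"u0", "u1", "u4", "u5", "u6"}
        out = hypergeom_enrich(net, PathwayDB({"pw": pw}), universe=universe)
        assert out.loc[0, "p_value"] == pytest.approx(3856 / 15504, rel=1e-12)
        assert out.loc[0, "expected"] == pytest.approx(4 * 5 / 20)

    def test_matches_subset_enumeration_oracle(self):
        """True enumeration of every draw for a small universe."""
        universe = [f"u{i}" for i in range(9)]
        pw = set(universe[:4])
        db = PathwayDB({"pw": pw})
        for draws in (2, 4, 6):
            for hits_net in range(draws + 1):
                net = set(universe[:hits_net]) | set(
                    universe[4:4 + draws - hits_net]
                )
                if len(net) != draws:
                    continue
                obs_hits = len(net & pw)
                count = sum(
                    1
                    for combo in itertools.combinations(universe, draws)
                    if len(set(combo) & pw) >= obs_hits
                )
                expected = count / math.comb(9, draws)
                out = hypergeom_enrich(net, db, universe=set(universe))
                assert out.loc[0, "p_value"] == pytest.approx(
                    expected, rel=1e-12
                )

    def test_matches_exact_fraction_oracle_across_configurations(self):
        """Sweep universes up to 25 against integer-combinatorics tail."""
        for n_u in (5, 10, 17, 25):
            universe = {f"u{i}" for i in range(n_u)}
            ulist = sorted(universe)
            for total in range(1, n_u + 1, 3):
                pw = set(ulist[:total])
                for draws in range(1, n_u + 1, 4):
                    for hits in range(0, min(total, draws) + 1):
                        net = set(ulist[:hits]) | set(
                            ulist[total:total + draws - hits]
                        )
                        if len(net & universe) != draws or len(net & pw) != hits:
                            continue
                        out = hypergeom_enrich(
                            net, PathwayDB({"pw": pw}), universe=universe
                        )
                        oracle = float(
                            hypergeom_tail_fraction(n_u, total, draws, hits)
                        )
                        assert out.loc[0, "p_value"] == pytest.approx(
                            oracle, rel=1e-10
                        )

    def test_pathway_outside_universe_rejected(self):
        db = PathwayDB({"pw": {"a", "zzz"}})
        with pytest.raises(ValueError, match="zzz"):
            hypergeom_enrich({"a"}, db, universe={"a", "b"})

    def test_expected_scales_linearly_with_total(self):
        universe = {f"u{i}" for i in range(100)}
        ulist = sorted(universe)
        net = set(ulist[:10])
        db = PathwayDB({"small": set(ulist[:5]), "large": set(ulist[:50])})
        out = hypergeom_enrich(net, db, universe=universe).set_index("pathway")
        ratio_small = out.loc["small", "expected"] / 5
        ratio_large = out.loc["large", "expected"] / 50
        assert ratio_small == pytest.approx(ratio_large)


class TestBhFdr:
    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.2], m=1), [0.2])

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03], m=3), [0.03, 0.03, 0.03]
        )

    def test_matches_statsmodels_when_m_equals_length(self, rng):
        p = rng.uniform(0, 1, 40)
        ours = bh_fdr(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_monotone_and_dominates_raw_p(self, rng):
        p = rng.uniform(0, 1, 25)
        adj = bh_fdr(p, m=30)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bh_fdr([1.2])
        with pytest.raises(ValueError):
            bh_fdr([0.1, 0.2], m=1)


class TestEmpiricalPvalues:
    def small_world(self, seed=0):
        cfg = simulate.SimulationConfig(
            seed=seed,
            n_genes=200,
            interactome_size=200,
            n_pathways=20,
            pathway_size_range=(5, 40),
        )
        inter = simulate.generate_interactome(cfg)
        seeds = sorted(inter.nodes)[:8]
        pw = simulate.generate_pathways(cfg, inter, seeds)
        return inter, pw, seeds

    def test_ratio_and_floor_token(self, rng):
        inter, pw, seeds = self.small_world()
        out = empirical_pathway_pvalues(
            inter, pw, list(pw.sets), list_size=8, r=10, seed=1
        )
        assert ((out["b"] / 10) == out["empirical_p"]).all()
        zero = out.loc[out["b"] == 0, "empirical_p_display"]
        assert (zero == "<0.1").all()

    def test_floor_display_at_r_100(self):
        inter, pw, seeds = self.small_world()
        out = empirical_pathway_pvalues(
            inter, pw, ["PW0001"], list_size=5, r=100, seed=2
        )
        row = out.iloc[0]
        if row["b"] == 0:
            assert row["empirical_p_display"] == "<0.01"
        else:
            assert row["empirical_p_display"] == str(row["empirical_p"])

    def test_fixed_seed_reproducible(self):
        inter, pw, seeds = self.small_world()
        a = empirical_pathway_pvalues(
            inter, pw, list(pw.sets), list_size=6, r=20, seed=9
        )
        b = empirical_pathway_pvalues(
            inter, pw, list(pw.sets), list_size=6, r=20, seed=9
        )
        pd.testing.assert_frame_equal(a, b)

    def test_list_size_exceeding_universe_rejected(self):
        inter, pw, _ = self.small_world()
        with pytest.raises(ValueError, match="exceeds universe"):
            empirical_pathway_pvalues(
                inter, pw, ["PW0001"], list_size=10_000, r=5, seed=0
            )


class TestNetworkEnrichmentModel:
    def test_planted_pathway_recovered_end_to_end(self):
        sim = simulate.study_scale_config(seed=42)
        inter = simulate.generate_interactome(
            sim, must_include=simulate.meth_genes(sim)
        )
        seeds = [f"G{i:04d}" for i in range(1, 12)]
        pw = simulate.generate_pathways(sim, inter, seeds)
        res = NetworkEnrichment(inter, pw, set(seeds)).fit(r=50, seed=0)
        t = res.table().set_index("pathway")
        assert t.loc["PW_PLANTED", "fdr"] < 0.05
        assert t.loc["PW_PLANTED", "empirical_p"] <= 0.05
        assert "pathways tested" in res.summary()

    def test_universe_default_is_annotated_interactome_genes(self):
        g = nx.path_graph(4)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(4)})
        pw = PathwayDB({"pw": {"n0", "n1", "zzz"}})
        model = NetworkEnrichment(g, pw, {"n0"})
        assert model.universe == {"n0", "n1"}
        assert model.pathways.sets["pw"] == {"n0", "n1"}

    def test_gmt_roundtrip(self, tmp_path):
        db = PathwayDB(
            {"a": {"g1", "g2"}, "b": {"g3"}}, {"a": "first", "b": "second"}
        )
        path = tmp_path / "sets.gmt"
        write_gmt(db, path)
        back = read_gmt(path)
        assert back.sets == db.sets
        assert back.descriptions == db.descriptions
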