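"""Synthetic-data generators: contracts, determinism, planted structure."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, hypergeom, kstest

from targetgene import simulate
from targetgene.expression import log2_transform, quantile_normalize
from targetgene.network import bh_fdr, first_order_network, hypergeom_enrich
from targetgene.simulate import SimulationConfig


class TestConfigValidation:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError, match="maf"):
            SimulationConfig(maf=0.7)
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError, match="FC"):
            SimulationConfig(planted_de=[("G0001", 0.5, "up")])
        with pytest.raises(ValueError, match="attachment"):
            SimulationConfig(
                n_genes=5, interactome_size=1, attachment=3
            )


class TestExpression:
    def test_shape_and_labels(self):
        cfg = SimulationConfig(
            seed=1, n_genes=100, n_cases=(5, 5), n_controls=(5, 5)
        )
        studies = simulate.generate_expression_studies(cfg)
        assert len(studies) == 2
        for s in studies:
            assert s.values.shape == (100, 10)
            assert (s.labels == "case").sum() == 5
            assert (s.labels == "control").sum() == 5
            assert (s.values.to_numpy() > 0).all()

    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(seed=7, n_genes=50, n_cases=(4,), n_controls=(4,))
        a = simulate.generate_expression_studies(cfg)[0]
        b = simulate.generate_expression_studies(cfg)[0]
        assert a.values.to_csv() == b.values.to_csv()

    def test_zero_noise_ratio_equals_planted_fc(self):
        cfg = SimulationConfig(
            seed=0,
            n_genes=10,
            n_cases=(4,),
            n_controls=(4,),
            planted_de=[("G0003", 2.0, "up"), ("G0005", 1.5, "down")],
            noise_sd=0.0,
        )
        s = simulate.generate_expression_studies(cfg)[0]
        log2 = np.log2(s.values)
        ratio = 2 ** (
            log2[s.case_samples].mean(axis=1)
            - log2[s.control_samples].mean(axis=1)
        )
        assert ratio["G0003"] == pytest.approx(2.0)
        assert ratio["G0005"] == pytest.approx(1 / 1.5)
        assert ratio["G0001"] == pytest.approx(1.0)


class TestGenotypes:
    def test_hardy_weinberg_frequencies_at_half(self):
        cfg = SimulationConfig(seed=3, n_subjects=10_000, n_snps=1, maf=0.5)
        g = simulate.generate_genotypes(cfg).iloc[:, 0]
        n = len(g)
        for k, expected in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            freq = (g == k).mean()
            sd = np.sqrt(expected * (1 - expected) / n)
            assert abs(freq - expected) < 3 * sd

    def test_tiny_maf_gives_all_zero_column(self):
        cfg = SimulationConfig(seed=0, n_subjects=100, n_snps=1, maf=1e-9)
        g = simulate.generate_genotypes(cfg)
        assert (g.to_numpy() == 0).all()

    def test_values_in_dosage_range_and_deterministic(self):
        cfg = SimulationConfig(seed=5, n_subjects=50, n_snps=4)
        a = simulate.generate_genotypes(cfg)
        b = simulate.generate_genotypes(cfg)
        pd.testing.assert_frame_equal(a, b)
        assert set(np.unique(a.to_numpy())) <= {0, 1, 2}


class TestMethylation:
    def test_zero_model_gives_constant_probe_columns(self):
        cfg = SimulationConfig(
            seed=2,
            n_subjects=20,
            meth_noise_sd=0.0,
            meth_covariate_effect_sd=0.0,
            eqtl_effects=[("rs900001", "G0001", 0.8)],
        )
        geno = simulate.generate_genotypes(cfg)
        m, _, _ = simulate.generate_methylation(cfg, geno)
        assert (m.nunique() == 1).all()

    def test_default_probe_count_per_gene(self):
        cfg = SimulationConfig(seed=0, n_subjects=10)
        geno = simulate.generate_genotypes(cfg)
        genes = ["G0001", "G0002", "G0003", "G0004"]
        m, cov, probe_map = simulate.generate_methylation(cfg, geno, genes)
        assert m.shape == (10, 44)  # 4 genes x 11 probes
        assert probe_map["gene"].value_counts().eq(11).all()
        assert list(cov.columns) == ["sex", "age"] + [
            f"pc{i + 1}" for i in range(10)
        ]


class TestInteractome:
    def test_node_and_edge_counts_and_connectivity(self):
        cfg = SimulationConfig(
            seed=1, n_genes=100, interactome_size=100, attachment=2
        )
        g = simulate.generate_interactome(cfg)
        assert g.number_of_nodes() == 100
        # preferential-attachment recurrence: m edges per added node
        assert g.number_of_edges() == 2 * (100 - 2)
        assert nx.is_connected(g)
        assert not any(g.has_edge(n, n) for n in g)

    def test_minimal_graph_single_edge(self):
        cfg = SimulationConfig(
            seed=0, n_genes=10, interactome_size=2, attachment=1
        )
        g = simulate.generate_interactome(cfg)
        assert g.number_of_edges() == 1

    def test_seeded_edge_list_identical_and_must_include(self):
        cfg = SimulationConfig(
            seed=4, n_genes=50, interactome_size=30, attachment=2
        )
        a = simulate.generate_interactome(cfg, must_include=["G0049"])
        b = simulate.generate_interactome(cfg, must_include=["G0049"])
        assert sorted(map(sorted, a.edges)) == sorted(map(sorted, b.edges))
        assert "G0049" in a


class TestPathways:
    def test_sizes_within_range_and_gmt_contract(self):
        cfg = SimulationConfig(
            seed=1,
            n_genes=300,
            interactome_size=300,
            n_pathways=50,
            pathway_size_range=(10, 150),
        )
        inter = simulate.generate_interactome(cfg)
        db = simulate.generate_pathways(cfg, inter)
        assert len(db.sets) == 50
        assert all(10 <= len(s) <= 150 for s in db.sets.values())

    def test_planted_pathway_flagged_by_enrichment_stage(self):
        hits = 0
        for rep in range(5):
            cfg = SimulationConfig(
                seed=100 + rep,
                n_genes=300,
                interactome_size=300,
                n_pathways=30,
                pathway_size_range=(5, 60),
            )
            inter = simulate.generate_interactome(cfg)
            seeds = [f"G{i:04d}" for i in range(1, 12) if f"G{i:04d}" in inter]
            db = simulate.generate_pathways(cfg, inter, seeds)
            universe = db.genes & set(inter.nodes)
            sub, _, _ = first_order_network(inter, set(seeds))
            enr = hypergeom_enrich(
                set(sub.nodes), db.restrict(universe), universe=universe
            )
            enr["fdr"] = bh_fdr(enr["p_value"].to_numpy())
            row = enr.set_index("pathway").loc["PW_PLANTED"]
            if row["fdr"] < 0.05:
                hits += 1
        assert hits >= 4

    def test_unplanted_hit_counts_follow_hypergeometric_null(self, rng):
        """Random draws vs one fixed pathway: hit counts match the
        hypergeometric pmf (chi-square goodness of fit)."""
        cfg = SimulationConfig(
            seed=9,
            n_genes=200,
            interactome_size=200,
            n_pathways=10,
            pathway_size_range=(30, 30),
        )
        inter = simulate.generate_interactome(cfg)
        db = simulate.generate_pathways(cfg, inter)
        universe = sorted(db.genes & set(inter.nodes))
        pw = db.sets["PW0001"] & set(universe)
        draws = 20
        counts = []
        for _ in range(400):
            lst = set(rng.choice(universe, size=draws, replace=False))
            counts.append(len(lst & pw))
        dist = hypergeom(len(universe), len(pw), draws)
        support = np.arange(0, draws + 1)
        expected = dist.pmf(support) * len(counts)
        observed = np.bincount(counts, minlength=draws + 1)
        keep = expected > 1.0
        stat = chisquare(
            observed[keep], expected[keep] * observed[keep].sum()
            / expected[keep].sum()
        )
        assert stat.pvalue > 0.01


class TestStudyScaleScenario:
    def test_eqtl_table_recovers_planted_effects(self):
        sim = simulate.study_scale_config(seed=11)
        geno = simulate.generate_genotypes(sim)
        table = simulate.generate_eqtl_table(sim, geno)
        planted = table.iloc[: len(sim.eqtl_effects)]
        assert (planted["p_value"] < 0.05).all()
        nulls = table.iloc[len(sim.eqtl_effects):]
        assert (nulls["slope"].abs() < 0.5).all()

    def test_null_eqtl_pvalues_roughly_uniform(self):
        sim = simulate.SimulationConfig(
            seed=21, n_subjects=100, n_null_eqtl_pairs=300
        )
        geno = simulate.generate_genotypes(sim)
        table = simulate.generate_eqtl_table(sim, geno)
        assert kstest(table["p_value"], "uniform").pvalue > 0.01

    def test_gwas_and_histone_tables_are_consistent(self):
        sim = simulate.study_scale_config(seed=2)
        snps = simulate.generate_gwas_snps(sim)
        assert len(snps) == 10
        assert snps["snp"].is_unique
        bed = simulate.generate_histone_intervals(sim, snps)
        assert (bed["start"] < bed["end"]).all()
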