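"""End-to-end orchestration: simulate -> preprocess -> rank product ->
eQTL filter -> integration -> meQTL -> network enrichment -> TSV reports.

The pipeline is driven by a :class:`PipelineConfig` (loadable from a
YAML file) and writes a report bundle: the SNP-gene target table, the
pathway enrichment table, the meQTL scan, the first-order network edge
list and a run log recording the seed, package versions and per-stage
timings, so a run can be reproduced exactly from its log.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__, io, simulate
from .eqtl import filter_eqtl
from .expression import log2_transform, quantile_normalize
from .integration import (
    GenomicInterval,
    annotate_histone_overlap,
    build_target_table,
)
from .methylation import MeqtlScan
from .network import NetworkEnrichment
from .rankprod import RankProduct

logger = logging.getLogger("targetgene")


@dataclass
class PipelineConfig:
    """Thresholds, seeds and sizes for one pipeline run."""

    seed: int = 0
    out_dir: str = "targetgene_run"
    eqtl_p: float = 0.05
    pfp: float = 0.05
    fc: float = 1.2
    enrich_fdr: float = 0.05
    alpha: float = 0.05
    b_permutations: int = 100
    r_resamples: int = 100
    pair_cap: int = 50
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("eqtl_p", "pfp", "enrich_fdr", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.fc <= 0:
            raise ValueError("fc threshold must be positive")
        if self.b_permutations < 1 or self.r_resamples < 1:
            raise ValueError("b_permutations and r_resamples must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def simulation_config(self) -> simulate.SimulationConfig:
        base = simulate.study_scale_config(seed=self.seed)
        if self.simulation:
            base = replace(base, **self.simulation)
        return base


class _EmptyEnrichment:
    """Stand-in results when no seed gene survives the filters."""

    def __init__(self, fdr_max: float):
        self.subgraph = nx.Graph()
        self.fdr_max = fdr_max
        self.missing_seeds: list[str] = []
        self._table = pd.DataFrame(
            columns=[
                "pathway", "total", "expected", "hits", "p_value", "fdr",
                "b", "empirical_p", "empirical_p_display",
            ]
        )

    def table(self) -> pd.DataFrame:
        return self._table.copy()

    @property
    def significant(self) -> pd.DataFrame:
        return self._table

    def summary(self) -> str:
        return "First-order network pathway enrichment\n(no seed genes)"


def _fmt(x: float) -> str:
    """Display form: 3 significant figures, scientific for small values."""
    if pd.isna(x):
        return ""
    if x != 0 and abs(x) < 1e-3:
        return np.format_float_scientific(x, precision=2)
    return f"{x:.3g}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a simulated cohort and write the report bundle.

    Returns a dict with the in-memory results: target table + counts,
    meQTL results, enrichment results, the network, and file paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.txt"
    handlers = [
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(log_path, mode="w"),
    ]
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
    logger.info(
        "targetgene %s | numpy %s pandas %s networkx %s | seed=%d",
        __version__, np.__version__, pd.__version__, nx.__version__,
        config.seed,
    )

    t0 = time.perf_counter()

    def stage(name):
        logger.info("stage %-12s @ %.1fs", name, time.perf_counter() - t0)

    sim = config.simulation_config()

    try:
        stage("simulate")
        studies = simulate.generate_expression_studies(sim)
        genotypes = simulate.generate_genotypes(sim)
        gwas_snps = simulate.generate_gwas_snps(sim)
        eqtl_table = simulate.generate_eqtl_table(sim, genotypes)
        histone = simulate.generate_histone_intervals(sim, gwas_snps)
        m_values, covariates, probe_map = simulate.generate_methylation(
            sim, genotypes
        )
    except Exception:
        logger.exception("stage 'simulate' failed")
        raise

    try:
        stage("preprocess")
        studies = [quantile_normalize(log2_transform(s)) for s in studies]
    except Exception:
        logger.exception("stage 'preprocess' failed")
        raise

    try:
        stage("rankprod")
        rp_model = RankProduct(studies, cap=config.pair_cap, seed=config.seed)
        rp_res = rp_model.fit(b=config.b_permutations)
    except Exception:
        logger.exception("stage 'rankprod' failed")
        raise

    try:
        stage("eqtl")
        eqtl_pass, eqtl_genes = filter_eqtl(eqtl_table, p_max=config.eqtl_p)
        logger.info(
            "eQTL: %d of %d associations pass p<%g over %d distinct genes",
            len(eqtl_pass), len(eqtl_table), config.eqtl_p, len(eqtl_genes),
        )
    except Exception:
        logger.exception("stage 'eqtl' failed")
        raise

    try:
        stage("integrate")
        target_table, counts = build_target_table(
            gwas_snps,
            eqtl_table,
            rp_res.table(),
            eqtl_p_max=config.eqtl_p,
            pfp_max=config.pfp,
            fc_min=config.fc,
        )
        intervals = [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.label)
            for r in histone.itertuples()
        ]
        target_table = annotate_histone_overlap(target_table, intervals)
        logger.info(
            "target table: %d pairs, %d genes (%d up / %d down), %d SNPs",
            counts["n_pairs"], counts["n_genes"], counts["n_up"],
            counts["n_down"], counts["n_snps"],
        )
    except Exception:
        logger.exception("stage 'integrate' failed")
        raise

    try:
        stage("methylation")
        snp_genes: dict[str, list[str]] = {}
        for row in target_table.itertuples():
            snp_genes.setdefault(row.snp, []).append(row.gene)
        meqtl_res = MeqtlScan(
            m_values, genotypes, covariates, probe_map, snp_genes
        ).fit(alpha=config.alpha)
        logger.info(
            "meQTL: %d pairs tested, cutoff %s, %d significant",
            meqtl_res.n_tests, meqtl_res.cutoff_display,
            meqtl_res.n_significant,
        )
    except Exception:
        logger.exception("stage 'methylation' failed")
        raise

    try:
        stage("network")
        target_genes = sorted(set(target_table["gene"]))
        interactome = simulate.generate_interactome(
            sim, must_include=simulate.meth_genes(sim)
        )
        pathways = simulate.generate_pathways(sim, interactome, target_genes)
        if target_genes:
            enr_model = NetworkEnrichment(
                interactome, pathways, set(target_genes)
            )
            enr_res = enr_model.fit(
                fdr_max=config.enrich_fdr,
                r=config.r_resamples,
                seed=config.seed,
            )
        else:
            logger.warning("no target genes pass the filters; empty network")
            enr_res = _EmptyEnrichment(config.enrich_fdr)
        logger.info(
            "network: %d nodes / %d edges; %d pathways FDR<%g",
            enr_res.subgraph.number_of_nodes(),
            enr_res.subgraph.number_of_edges(),
            len(enr_res.significant), config.enrich_fdr,
        )
    except Exception:
        logger.exception("stage 'network' failed")
        raise

    stage("report")
    tt = target_table.copy()
    for col in ("gwas_p", "eqtl_p", "pfp", "fc"):
        tt[f"{col}_display"] = tt[col].map(_fmt)
    io.write_table(tt, out / "target_table.tsv")

    et = enr_res.table()
    et["p_value_display"] = et["p_value"].map(_fmt)
    et["fdr_display"] = et["fdr"].map(_fmt)
    io.write_table(et, out / "enrichment.tsv")

    mt = meqtl_res.table()
    mt["p_value_display"] = mt["p_value"].map(_fmt)
    io.write_table(mt, out / "meqtl.tsv")

    io.write_edge_list(enr_res.subgraph, out / "network_edges.tsv")
    logger.info("done @ %.1fs -> %s", time.perf_counter() - t0, out)
    for h in handlers:
        h.close()
        logging.getLogger().removeHandler(h)

    return {
        "config": config,
        "target_table": target_table,
        "counts": counts,
        "rankprod": rp_res,
        "meqtl": meqtl_res,
        "enrichment": enr_res,
        "paths": {
            "target_table": out / "target_table.tsv",
            "enrichment": out / "enrichment.tsv",
            "meqtl": out / "meqtl.tsv",
            "network_edges": out / "network_edges.tsv",
            "run_log": log_path,
        },
    }


def write_simulated_inputs(config: PipelineConfig, out_dir) -> dict:
    """Materialise every synthetic input of a run as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation_config()
    paths = {}
    for study in simulate.generate_expression_studies(sim):
        v, l = io.write_expression_study(study, out)
        paths[f"{study.study_id}_expression"] = v
        paths[f"{study.study_id}_labels"] = l
    genotypes = simulate.generate_genotypes(sim)
    io.write_matrix(genotypes, out / "genotypes.tsv", "subject")
    m_values, covariates, probe_map = simulate.generate_methylation(
        sim, genotypes
    )
    io.write_matrix(m_values, out / "methylation_m_values.tsv", "subject")
    io.write_matrix(covariates, out / "covariates.tsv", "subject")
    io.write_table(probe_map, out / "probe_map.tsv")
    io.write_table(simulate.generate_gwas_snps(sim), out / "gwas_snps.tsv")
    io.write_table(
        simulate.generate_eqtl_table(sim, genotypes), out / "eqtl.tsv"
    )
    hist = simulate.generate_histone_intervals(
        sim, simulate.generate_gwas_snps(sim)
    )
    io.write_bed(hist.to_dict("records"), out / "histone.bed")
    interactome = simulate.generate_interactome(
        sim, must_include=simulate.meth_genes(sim)
    )
    io.write_edge_list(interactome, out / "interactome_edges.tsv")
    from .network import write_gmt

    write_gmt(
        simulate.generate_pathways(sim, interactome, simulate.meth_genes(sim)),
        out / "pathways.gmt",
    )
    paths.update(
        {
            p.stem: p
            for p in out.iterdir()
            if p.suffix in {".tsv", ".bed", ".gmt"}
        }
    )
    return paths
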