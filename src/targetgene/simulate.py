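"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator draws from a substream derived from one master seed
(``SimulationConfig.seed``), so a fixed config reproduces every file
byte-for-byte. The generated data emulate the study design the pipeline
targets: two neutrophil microarray cohorts totalling 36 cases and 26
controls (split evenly per cohort by default; the true split is a free
parameter), log-normal expression noise with differentially expressed
genes planted at stated fold changes, Hardy-Weinberg genotypes at a
given minor-allele frequency, methylation M-values linear in dosage plus
sex/age/PC covariates, a scale-free (preferential-attachment)
interactome, and pathway gene sets with one set planted to overlap the
seed genes' first-order neighbourhood.

Gene universe: synthetic symbols ``G0001`` ... — no real annotation is
shipped or implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import eqtl as eqtl_mod
from .expression import CASE, CONTROL, ExpressionStudy
from .network import PathwayDB

# named substreams of the master seed (documented, stable)
_STREAMS = {
    "expression": 11,
    "genotypes": 12,
    "methylation": 13,
    "interactome": 14,
    "pathways": 15,
    "gwas": 16,
    "eqtl": 17,
    "histone": 18,
}


def gene_universe(n_genes: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n_genes)]


def probe_id(gene: str, j: int) -> str:
    """Deterministic cg-style probe id for probe ``j`` of ``gene``."""
    return f"cg{int(gene.lstrip('G')):06d}{j:02d}"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-scale defaults."""

    seed: int = 0
    n_genes: int = 1000
    # per-study case/control sizes; totals default to the 36/26 design
    n_cases: tuple[int, ...] = (18, 18)
    n_controls: tuple[int, ...] = (13, 13)
    planted_de: list[tuple[str, float, str]] = field(default_factory=list)
    noise_sd: float = 0.3
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0

    n_snps: int = 10
    maf: float = 0.3
    n_subjects: int = 200
    eqtl_effects: list[tuple[str, str, float]] = field(default_factory=list)
    eqtl_noise_sd: float = 1.0
    n_null_eqtl_pairs: int = 20

    n_probes_per_gene: int = 11
    meqtl_effects: list[tuple[str, str, float]] = field(default_factory=list)
    meth_noise_sd: float = 0.1
    meth_covariate_effect_sd: float = 0.1
    meth_intercept_sd: float = 1.0

    interactome_size: int | None = None  # defaults to n_genes
    attachment: int = 2
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 150)
    planted_pathway_size: int = 15
    planted_from_neighborhood: int = 10

    def __post_init__(self) -> None:
        if self.interactome_size is None:
            self.interactome_size = self.n_genes
        if len(self.n_cases) != len(self.n_controls):
            raise ValueError("n_cases and n_controls must pair up per study")
        counts = [
            self.n_genes, self.n_snps, self.n_subjects,
            self.n_probes_per_gene, self.interactome_size, self.n_pathways,
            *self.n_cases, *self.n_controls,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.noise_sd < 0 or self.meth_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for gene, fc, direction in self.planted_de:
            if fc < 1.0:
                raise ValueError(f"planted FC for {gene} must be >= 1")
            if direction not in ("up", "down"):
                raise ValueError(f"planted direction {direction!r}")
        if self.interactome_size < self.attachment:
            raise ValueError("interactome_size must be >= attachment")
        if self.interactome_size > self.n_genes:
            raise ValueError("interactome cannot exceed the gene universe")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ValueError("pathway_size_range out of bounds")

    @property
    def n_studies(self) -> int:
        return len(self.n_cases)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])


def snp_ids(config: SimulationConfig) -> list[str]:
    return [f"rs9{i + 1:05d}" for i in range(config.n_snps)]


def generate_expression_studies(
    config: SimulationConfig,
) -> list[ExpressionStudy]:
    """Two-class log-normal expression with planted fold changes.

    Per study, per gene: log2 intensity = baseline + N(0, noise_sd),
    with the case class shifted by +/- log2(planted FC) for planted
    genes. Intensities are exponentiated so downstream preprocessing
    re-applies the log2. With noise_sd = 0 the case/control geometric
    mean ratio equals the planted FC exactly.
    """
    rng = config.rng("expression")
    genes = gene_universe(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    studies = []
    for s, (nca, nco) in enumerate(zip(config.n_cases, config.n_controls)):
        study_id = f"SIM{s + 1:02d}"
        samples = [f"{study_id}_S{j + 1:03d}" for j in range(nca + nco)]
        labels = pd.Series(
            [CASE] * nca + [CONTROL] * nco, index=samples, name="label"
        )
        baseline = rng.normal(
            config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
        )
        log2 = baseline[:, None] + rng.normal(
            0.0, config.noise_sd, (config.n_genes, nca + nco)
        )
        for gene, fc, direction in config.planted_de:
            shift = np.log2(fc) * (1 if direction == "up" else -1)
            log2[gene_pos[gene], :nca] += shift
        values = pd.DataFrame(
            np.power(2.0, log2), index=genes, columns=samples
        )
        studies.append(ExpressionStudy(study_id, values, labels))
    return studies


def generate_genotypes(config: SimulationConfig) -> pd.DataFrame:
    """Subjects x SNPs additive dosages, Binomial(2, maf) per entry
    (Hardy-Weinberg equilibrium)."""
    rng = config.rng("genotypes")
    subjects = [f"SUBJ{i + 1:04d}" for i in range(config.n_subjects)]
    geno = rng.binomial(2, config.maf, (config.n_subjects, config.n_snps))
    return pd.DataFrame(geno, index=subjects, columns=snp_ids(config))


def meth_genes(config: SimulationConfig) -> list[str]:
    """Genes carrying methylation probes: targets of the eQTL effects."""
    return list(dict.fromkeys(g for _, g, _ in config.eqtl_effects))


def generate_methylation(
    config: SimulationConfig,
    genotypes: pd.DataFrame,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """M-values linear in dosage, covariates and Gaussian noise.

    Per probe: M = intercept + slope * dosage (planted pairs only)
    + beta_sex * sex + beta_age * age + sum_i beta_i * PC_i + noise,
    with probe-specific covariate coefficients ~ N(0,
    meth_covariate_effect_sd). Returns (M-value matrix subjects x
    probes, covariate table, probe->gene map).
    """
    if genes is None:
        genes = meth_genes(config)
    rng = config.rng("methylation")
    subjects = genotypes.index
    n = len(subjects)
    sex = rng.integers(0, 2, n).astype(float)
    age = rng.uniform(20.0, 70.0, n)
    pcs = rng.normal(0.0, 1.0, (n, 10))
    covariates = pd.DataFrame(
        np.column_stack([sex, age, pcs]),
        index=subjects,
        columns=["sex", "age"] + [f"pc{i + 1}" for i in range(10)],
    )
    planted = {(s, p): b for s, p, b in config.meqtl_effects}
    probes, probe_genes, cols = [], [], []
    for gene in genes:
        for j in range(config.n_probes_per_gene):
            pid = probe_id(gene, j)
            intercept = rng.normal(0.0, config.meth_intercept_sd)
            betas = rng.normal(0.0, config.meth_covariate_effect_sd, 12)
            m = (
                intercept
                + betas[0] * sex
                + betas[1] * age
                + pcs @ betas[2:]
                + rng.normal(0.0, config.meth_noise_sd, n)
            )
            for snp in genotypes.columns:
                slope = planted.get((snp, pid))
                if slope:
                    m = m + slope * genotypes[snp].to_numpy(dtype=float)
            probes.append(pid)
            probe_genes.append(gene)
            cols.append(m)
    m_values = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((n, 0)),
        index=subjects,
        columns=probes,
    )
    probe_map = pd.DataFrame({"probe": probes, "gene": probe_genes})
    return m_values, covariates, probe_map


def generate_interactome(
    config: SimulationConfig, must_include: list[str] | None = None
) -> nx.Graph:
    """Connected scale-free graph (preferential attachment) with nodes
    labelled by gene symbols from the universe.

    ``must_include`` genes are guaranteed to be among the node labels
    (so planted seed genes are never absent by sampling accident).
    """
    rng = config.rng("interactome")
    g = nx.barabasi_albert_graph(
        config.interactome_size,
        config.attachment,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    universe = gene_universe(config.n_genes)
    must = list(dict.fromkeys(must_include or []))
    unknown = [m for m in must if m not in set(universe)]
    if unknown:
        raise ValueError(f"must_include outside the gene universe: {unknown}")
    rest = [u for u in universe if u not in set(must)]
    rng.shuffle(rest)
    labels = (must + rest)[: config.interactome_size]
    rng.shuffle(labels)
    return nx.relabel_nodes(g, dict(zip(g.nodes, labels)))


def generate_pathways(
    config: SimulationConfig,
    interactome: nx.Graph,
    seeds: list[str] | None = None,
) -> PathwayDB:
    """Random pathway sets plus one planted, neighbourhood-enriched set.

    Unplanted sets are uniform draws from the interactome's node labels.
    When ``seeds`` is given, the set ``PW_PLANTED`` takes
    ``planted_from_neighborhood`` genes from the seeds' first-order
    neighbourhood and fills up to ``planted_pathway_size`` from outside
    it, making it enriched far above chance in the seeds' first-order
    network.
    """
    rng = config.rng("pathways")
    nodes = sorted(interactome.nodes)
    lo, hi = config.pathway_size_range
    if hi > len(nodes):
        raise ValueError(
            f"pathway sizes up to {hi} impossible with {len(nodes)} genes"
        )
    sets, desc = {}, {}
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(nodes, size=size, replace=False)
        name = f"PW{i + 1:04d}"
        sets[name] = set(members.tolist())
        desc[name] = "random synthetic pathway"
    if seeds:
        present = [s for s in seeds if s in interactome]
        hood = set(present)
        for s in present:
            hood |= set(interactome.neighbors(s))
        hood_list = sorted(hood)
        k_in = min(config.planted_from_neighborhood, len(hood_list))
        inside = rng.choice(hood_list, size=k_in, replace=False).tolist()
        outside_pool = sorted(set(nodes) - hood)
        k_out = min(
            config.planted_pathway_size - k_in, len(outside_pool)
        )
        outside = rng.choice(outside_pool, size=k_out, replace=False).tolist()
        sets["PW_PLANTED"] = set(inside + outside)
        desc["PW_PLANTED"] = "planted seed-neighbourhood-enriched pathway"
    return PathwayDB(sets, desc)


def generate_gwas_snps(config: SimulationConfig) -> pd.DataFrame:
    """GWAS SNP list: rsID, chromosome, 1-based position, GWAS p."""
    rng = config.rng("gwas")
    ids = snp_ids(config)
    chrom = rng.integers(1, 23, config.n_snps).astype(str)
    pos = rng.integers(10_000, 200_000_000, config.n_snps)
    gwas_p = np.power(10.0, -rng.uniform(6.0, 15.0, config.n_snps))
    return pd.DataFrame(
        {"snp": ids, "chrom": chrom, "pos": pos, "gwas_p": gwas_p}
    )


def generate_eqtl_table(
    config: SimulationConfig, genotypes: pd.DataFrame
) -> pd.DataFrame:
    """eQTL association table computed from a simulated cohort.

    For each configured (snp, gene, slope) effect — and for
    ``n_null_eqtl_pairs`` slope-0 pairs — per-subject expression is
    drawn as baseline + slope * dosage + N(0, eqtl_noise_sd) and the
    additive regression of the eQTL stage produces the slope and p.
    """
    rng = config.rng("eqtl")
    genes = gene_universe(config.n_genes)
    effect_pairs = [(s, g, b) for s, g, b in config.eqtl_effects]
    used = {(s, g) for s, g, _ in effect_pairs}
    null_pairs = []
    snps = list(genotypes.columns)
    while len(null_pairs) < config.n_null_eqtl_pairs:
        s = snps[int(rng.integers(0, len(snps)))]
        g = genes[int(rng.integers(0, len(genes)))]
        if (s, g) not in used:
            used.add((s, g))
            null_pairs.append((s, g, 0.0))
    records = []
    for snp, gene, slope in effect_pairs + null_pairs:
        dosage = genotypes[snp].to_numpy(dtype=float)
        expr = (
            config.baseline_log2_mean
            + slope * dosage
            + rng.normal(0.0, config.eqtl_noise_sd, dosage.size)
        )
        records.append(
            eqtl_mod.additive_eqtl_regression(
                dosage, expr, snp=snp, gene=gene
            )
        )
    return eqtl_mod.records_to_frame(records)


def generate_histone_intervals(
    config: SimulationConfig, gwas_snps: pd.DataFrame
) -> pd.DataFrame:
    """Histone-mark BED intervals; roughly half the SNPs get a covering
    interval, the rest of the intervals are placed at random."""
    rng = config.rng("histone")
    marks = ["H3K4me1_Enh", "H3K4me3_Pro", "H3K27ac_Enh", "H3K9ac_Pro"]
    rows = []
    for _, snp in gwas_snps.iterrows():
        if rng.random() < 0.5:
            width = int(rng.integers(200, 2000))
            offset = int(rng.integers(0, width))
            start = max(0, int(snp["pos"]) - 1 - offset)
            rows.append(
                {
                    "chrom": str(snp["chrom"]),
                    "start": start,
                    "end": start + width,
                    "label": marks[int(rng.integers(0, len(marks)))],
                }
            )
    for _ in range(30):
        chrom = str(int(rng.integers(1, 23)))
        start = int(rng.integers(10_000, 200_000_000))
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + int(rng.integers(200, 2000)),
                "label": marks[int(rng.integers(0, len(marks)))],
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["chrom", "start"], kind="stable"
    ).reset_index(drop=True)


def study_scale_config(seed: int = 0) -> SimulationConfig:
    """Config emulating the case study's scale and structure.

    Two cohorts of 18/13 cases/controls (36/26 total); 10 GWAS SNPs
    mapping to 13 eQTL target pairs over 11 genes (two SNP pairs share
    their two genes, as in the published table), 5 planted up- and 6
    down-regulated at FC 1.5; extra eQTL-only and DE-only genes so the
    intersection is a proper filter; ~143 SNP x probe methylation tests
    with 4 planted meQTL effects; a 1000-node preferential-attachment
    interactome and 50 pathways plus one planted around the target
    genes' neighbourhood.
    """
    up = [f"G{i:04d}" for i in range(1, 6)]
    down = [f"G{i:04d}" for i in range(6, 12)]
    de_only = [f"G{i:04d}" for i in range(20, 24)]
    planted_de = (
        [(g, 1.5, "up") for g in up]
        + [(g, 1.5, "down") for g in down]
        + [(g, 1.5, "up") for g in de_only]
    )
    eqtl_effects = [(f"rs9{i:05d}", f"G{i:04d}", 0.8) for i in range(1, 8)]
    eqtl_effects += [
        ("rs900008", "G0008", 0.8),
        ("rs900008", "G0009", 0.8),
        ("rs900009", "G0010", 0.8),
        ("rs900009", "G0011", 0.8),
        ("rs900010", "G0010", 0.8),
        ("rs900010", "G0011", 0.8),
    ]
    # eQTL-only genes (no differential expression planted)
    eqtl_effects += [
        (f"rs9{(i % 10) + 1:05d}", f"G{i + 12:04d}", 0.8) for i in range(8)
    ]
    meqtl_effects = [
        ("rs900001", probe_id("G0001", 0), 0.8),
        ("rs900003", probe_id("G0003", 0), 0.8),
        ("rs900008", probe_id("G0008", 0), 0.8),
        ("rs900009", probe_id("G0010", 0), 0.8),
    ]
    return SimulationConfig(
        seed=seed,
        planted_de=planted_de,
        eqtl_effects=eqtl_effects,
        meqtl_effects=meqtl_effects,
    )
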