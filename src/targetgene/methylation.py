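"""Genotype vs DNA-methylation (meQTL) regression with a family-wise cutoff.

Each SNP is tested against the M-values (log2 methylated/unmethylated
intensity ratio) of the probes in its target gene(s) with an OLS model
adjusted for sex, age and 10 genotype-derived principal components. The
experiment-wide significance threshold is the Bonferroni cutoff
alpha / n_tests over all SNP-probe pairs tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

N_PCS = 10
COVARIATE_COLUMNS = ["sex", "age"] + [f"pc{i + 1}" for i in range(N_PCS)]


@dataclass
class MeqtlRecord:
    snp: str
    probe: str
    gene: str
    slope: float
    p_value: float
    testable: bool = True
    note: str = ""
    significant: bool = False


def meqtl_regression(
    m_values: np.ndarray,
    genotypes: np.ndarray,
    covariates: pd.DataFrame,
    snp: str = "snp",
    probe: str = "probe",
    gene: str = "gene",
) -> MeqtlRecord:
    """OLS of probe M-values on dosage + sex + age + 10 PCs + intercept.

    Two-sided t-test on the genotype slope. Designs that cannot support
    the model — too few subjects for the 13 predictors plus intercept,
    constant genotype, or a rank-deficient covariate block — yield an
    untestable record carrying a diagnostic note instead of raising.
    """
    m = np.asarray(m_values, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    missing = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing}")
    cov = covariates[COVARIATE_COLUMNS].to_numpy(dtype=float)
    if not (m.shape[0] == g.shape[0] == cov.shape[0]):
        raise ValueError("M-values, genotypes and covariates differ in length")

    def untestable(note: str) -> MeqtlRecord:
        return MeqtlRecord(
            snp, probe, gene, np.nan, np.nan, testable=False, note=note
        )

    n_predictors = 1 + cov.shape[1]  # genotype + covariates
    if m.shape[0] <= n_predictors + 1:
        return untestable(
            f"n={m.shape[0]} subjects cannot fit {n_predictors} predictors "
            "plus intercept"
        )
    if np.ptp(g) == 0:
        return untestable("constant genotype")
    design = sm.add_constant(np.column_stack([g, cov]))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return untestable("rank-deficient design")
    fit = sm.OLS(m, design).fit()
    return MeqtlRecord(
        snp, probe, gene, float(fit.params[1]), float(fit.pvalues[1])
    )


def bonferroni_cutoff(alpha: float, n_tests: int) -> tuple[float, str]:
    """Family-wise cutoff alpha / n_tests, with a 2-significant-figure
    display string (e.g. (0.05, 144) -> 3.472e-4, shown "3.5e-04")."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    cutoff = alpha / n_tests
    return cutoff, np.format_float_scientific(cutoff, precision=1)


def count_significant(
    records: pd.DataFrame, cutoff: float
) -> tuple[int, pd.DataFrame]:
    """Count records with p strictly below the cutoff and flag them."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    flagged = records.copy()
    flagged["significant"] = flagged["p_value"] < cutoff
    return int(flagged["significant"].sum()), flagged


class MeqtlScan:
    """Scan every SNP x (probe in its target genes) pair.

    Parameters
    ----------
    m_values : pandas.DataFrame
        Subjects x probes M-value matrix.
    genotypes : pandas.DataFrame
        Subjects x SNPs dosage matrix (0/1/2).
    covariates : pandas.DataFrame
        Subjects x {sex, age, pc1..pc10}.
    probe_map : pandas.DataFrame
        Columns ``probe``, ``gene`` mapping probes to genes.
    snp_genes : mapping
        SNP id -> iterable of its target gene ids (the pairs emerging
        from the integration stage).
    """

    def __init__(self, m_values, genotypes, covariates, probe_map, snp_genes):
        self.m_values = m_values
        self.genotypes = genotypes
        self.covariates = covariates
        self.probe_map = probe_map
        self.snp_genes = snp_genes

    def fit(self, alpha: float = 0.05) -> "MeqtlScanResults":
        subjects = self.m_values.index.intersection(
            self.genotypes.index
        ).intersection(self.covariates.index)
        cov = self.covariates.loc[subjects]
        by_gene = self.probe_map.groupby("gene")["probe"]
        records = []
        for snp, genes in self.snp_genes.items():
            for gene in genes:
                if gene not in by_gene.groups:
                    continue
                for probe in by_gene.get_group(gene):
                    records.append(
                        meqtl_regression(
                            self.m_values.loc[subjects, probe].to_numpy(),
                            self.genotypes.loc[subjects, snp].to_numpy(),
                            cov,
                            snp=snp,
                            probe=probe,
                            gene=gene,
                        )
                    )
        columns = ["snp", "probe", "gene", "slope", "p_value", "testable", "note"]
        table = pd.DataFrame(
            [
                {
                    "snp": r.snp,
                    "probe": r.probe,
                    "gene": r.gene,
                    "slope": r.slope,
                    "p_value": r.p_value,
                    "testable": r.testable,
                    "note": r.note,
                }
                for r in records
            ],
            columns=columns,
        )
        return MeqtlScanResults(self, table, alpha)


class MeqtlScanResults:
    """Fitted meQTL scan with the experiment-wide Bonferroni threshold."""

    def __init__(self, model: MeqtlScan, table: pd.DataFrame, alpha: float):
        self.model = model
        self.alpha = alpha
        self.n_tests = int(table["testable"].sum()) if len(table) else 0
        if self.n_tests:
            self.cutoff, self.cutoff_display = bonferroni_cutoff(
                alpha, self.n_tests
            )
            n_sig, table = count_significant(table, self.cutoff)
            self.n_significant = n_sig
        else:
            self.cutoff = np.nan
            self.cutoff_display = "n/a"
            self.n_significant = 0
            table = table.assign(significant=pd.Series(dtype=bool))
        self._table = table

    def table(self) -> pd.DataFrame:
        return self._table.copy()

    def summary(self) -> str:
        return "\n".join(
            [
                "meQTL scan (M-value ~ dosage + sex + age + 10 PCs)",
                "==================================================",
                f"SNP-probe pairs tested:    {self.n_tests}",
                f"alpha:                     {self.alpha}",
                f"experiment-wide cutoff:    {self.cutoff_display} "
                f"({self.cutoff:.4e})",
                f"significant pairs:         {self.n_significant}",
            ]
        )
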