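"""SNP-to-gene expression association (eQTL) testing and filtering.

Associations use the additive model standard in eQTL mapping: expression
is regressed on allele dosage (0/1/2) with an intercept and the slope is
tested two-sided. Externally produced association tables (portal-style
TSV exports) can alternatively be filtered directly at a nominal
p-value threshold; no multiple-testing correction is applied at this
stage, since downstream integration with differential expression serves
as the orthogonal filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class EqtlRecord:
    """One SNP-gene association: additive slope and two-sided p."""

    snp: str
    gene: str
    slope: float
    p_value: float
    tissue: str = "whole blood"
    testable: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.testable and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.snp}-{self.gene}: p outside [0,1]")


def additive_eqtl_regression(
    genotypes: np.ndarray,
    expression: np.ndarray,
    snp: str = "snp",
    gene: str = "gene",
    tissue: str = "whole blood",
) -> EqtlRecord:
    """OLS of expression on genotype dosage with intercept.

    A constant genotype vector makes the slope inestimable; the record is
    returned flagged untestable (p = NaN) rather than raising, so a batch
    over many SNPs survives monomorphic ones.
    """
    g = np.asarray(genotypes, dtype=float)
    e = np.asarray(expression, dtype=float)
    if g.shape != e.shape or g.ndim != 1:
        raise ValueError("genotype and expression must be equal-length vectors")
    if g.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(g) == 0:
        return EqtlRecord(
            snp, gene, np.nan, np.nan, tissue,
            testable=False, note="constant genotype",
        )
    fit = sm.OLS(e, sm.add_constant(g)).fit()
    return EqtlRecord(
        snp, gene, float(fit.params[1]), float(fit.pvalues[1]), tissue
    )


def eqtl_scan(
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    pairs: list[tuple[str, str]],
    tissue: str = "whole blood",
) -> pd.DataFrame:
    """Run the additive regression for each (snp, gene) pair.

    ``genotypes``: subjects x SNPs dosage matrix; ``expression``:
    subjects x genes. Subjects are aligned on the index.
    """
    subjects = genotypes.index.intersection(expression.index)
    records = []
    for snp, gene in pairs:
        rec = additive_eqtl_regression(
            genotypes.loc[subjects, snp].to_numpy(),
            expression.loc[subjects, gene].to_numpy(),
            snp=snp,
            gene=gene,
            tissue=tissue,
        )
        records.append(rec)
    return records_to_frame(records)


def records_to_frame(records: list[EqtlRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp": r.snp,
                "gene": r.gene,
                "slope": r.slope,
                "p_value": r.p_value,
                "tissue": r.tissue,
                "testable": r.testable,
                "note": r.note,
            }
            for r in records
        ]
    )


def read_eqtl_table(path) -> pd.DataFrame:
    """Read a portal-style eQTL TSV (snp, gene, [slope,] p, ...).

    Column names are matched case-insensitively against common export
    dialects; extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    snp = pick("snp", "snp_id", "rsid", "variant_id")
    gene = pick("gene", "gene_id", "gene_symbol", "gencode_id")
    p = pick("p_value", "p", "pval", "pvalue", "p-value")
    if snp is None or gene is None or p is None:
        raise ValueError(
            f"eQTL table {path}: need snp, gene and p-value columns, "
            f"found {list(df.columns)}"
        )
    out = pd.DataFrame({"snp": df[snp], "gene": df[gene], "p_value": df[p]})
    slope = pick("slope", "beta", "effect_size", "nes")
    out["slope"] = df[slope] if slope is not None else np.nan
    return out


def filter_eqtl(
    records: pd.DataFrame, p_max: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Keep associations with p strictly below ``p_max``.

    Input order is preserved; untestable records (p = NaN) never pass.
    Returns the filtered frame and the list of distinct genes it covers
    (in first-appearance order).
    """
    if not (0.0 < p_max <= 1.0):
        raise ValueError("p_max must be in (0, 1]")
    kept = records.loc[records["p_value"] < p_max].copy()
    genes = list(dict.fromkeys(kept["gene"]))
    return kept, genes
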