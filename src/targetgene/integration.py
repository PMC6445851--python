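"""Intersect eQTL genes with DEGs into the SNP-gene target table.

A (SNP, gene) pair enters the table only if the eQTL association has
p < 0.05, the gene's differential-expression PFP is < 0.05 and its
|fold change| > 1.2 — all strict. SNP positions are 1-based; histone
intervals come from BED (0-based half-open), so a SNP at position p
overlaps [s, e) iff s <= p-1 < e. That conversion happens in exactly
one place (:func:`annotate_histone_overlap`).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class GenomicInterval:
    """A labelled 0-based half-open interval, BED convention."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(start >= end)"
            )


def read_bed(path) -> list[GenomicInterval]:
    """Read 3+-column BED; column 4 (name), when present, is the label."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            label = parts[3] if len(parts) > 3 else ""
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), label)
            )
    return out


def build_target_table(
    gwas_snps: pd.DataFrame,
    eqtl_records: pd.DataFrame,
    deg_results: pd.DataFrame,
    eqtl_p_max: float = 0.05,
    pfp_max: float = 0.05,
    fc_min: float = 1.2,
    annotations: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Build the SNP-gene target table and its headline counts.

    Parameters
    ----------
    gwas_snps : DataFrame with columns snp, chrom, pos, gwas_p
        1-based positions as printed in GWAS summaries.
    eqtl_records : DataFrame with columns snp, gene, p_value
    deg_results : DataFrame indexed by gene with columns pfp_up,
        pfp_down, fc (a :class:`RankProductResults` table).
    annotations : optional DataFrame with columns snp, gene, location
        (5'/3'/intron/exon), merged in when given; location is taken
        from existing annotation, never computed.

    Returns
    -------
    table : DataFrame
        One row per passing (SNP, gene) pair, sorted by chromosome then
        position, with eQTL p, PFP, signed FC and direction.
    counts : dict
        n_pairs, n_genes, n_snps, n_up, n_down (directions over
        distinct genes).
    """
    known_snps = set(gwas_snps["snp"])
    stray = sorted(set(eqtl_records["snp"]) - known_snps)
    if stray:
        raise ValueError(
            f"eQTL records reference SNPs absent from the GWAS list: {stray}"
        )

    eqtl_pass = eqtl_records.loc[eqtl_records["p_value"] < eqtl_p_max]
    best_pfp = deg_results[["pfp_up", "pfp_down"]].min(axis=1)
    deg_pass = deg_results.loc[
        (best_pfp < pfp_max) & (deg_results["fc"].abs() > fc_min)
    ]

    rows = eqtl_pass.loc[eqtl_pass["gene"].isin(deg_pass.index)].copy()
    rows = rows.rename(columns={"p_value": "eqtl_p"})
    rows = rows.merge(
        gwas_snps[["snp", "chrom", "pos", "gwas_p"]], on="snp", how="left"
    )
    deg_cols = deg_pass[["pfp_up", "pfp_down", "fc"]]
    rows = rows.merge(deg_cols, left_on="gene", right_index=True, how="left")
    rows["pfp"] = rows[["pfp_up", "pfp_down"]].min(axis=1)
    rows["direction"] = rows["fc"].map(lambda f: "up" if f > 0 else "down")
    if annotations is not None:
        rows = rows.merge(
            annotations[["snp", "gene", "location"]],
            on=["snp", "gene"],
            how="left",
        )
    else:
        rows["location"] = pd.NA

    def chrom_key(c):
        s = str(c).removeprefix("chr")
        return (0, int(s)) if s.isdigit() else (1, s)

    rows = rows.sort_values(
        by=["chrom", "pos", "gene"],
        key=lambda col: col.map(chrom_key) if col.name == "chrom" else col,
        kind="stable",
    ).reset_index(drop=True)
    cols = [
        "snp", "chrom", "pos", "gene", "location",
        "gwas_p", "eqtl_p", "pfp", "fc", "direction",
    ]
    table = rows[cols]
    n_up, n_down = classify_direction(table)
    counts = {
        "n_pairs": len(table),
        "n_genes": table["gene"].nunique(),
        "n_snps": table["snp"].nunique(),
        "n_up": n_up,
        "n_down": n_down,
    }
    return table, counts


def classify_direction(table: pd.DataFrame) -> tuple[int, int]:
    """Up/down counts over distinct genes (a gene reached by several
    SNPs is counted once; FC sign is per gene, so duplicates agree)."""
    per_gene = table.drop_duplicates("gene")
    n_up = int((per_gene["fc"] > 0).sum())
    n_down = int((per_gene["fc"] < 0).sum())
    return n_up, n_down


def annotate_histone_overlap(
    table: pd.DataFrame, intervals: list[GenomicInterval]
) -> pd.DataFrame:
    """Attach all histone-mark labels whose interval covers each SNP.

    The single 1-based -> 0-based conversion of the package: SNP at
    printed position p occupies base p-1 in BED coordinates.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, iv.label
        )
    marks = []
    for _, row in table.iterrows():
        tree = trees.get(str(row["chrom"]))
        base = int(row["pos"]) - 1
        if tree is None:
            marks.append([])
            continue
        hits = sorted(hit.data for hit in tree.at(base))
        marks.append(hits)
    out = table.copy()
    out["histone_marks"] = [" ".join(m) for m in marks]
    return out
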