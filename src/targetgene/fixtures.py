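"""Bundled case-study tables from the JIA neutrophil analysis.

``table1`` holds the 13 published SNP-gene target pairs (GWAS and eQTL
p-values, rank-product PFP, signed fold change, histone-mark overlap
and methylation probe results) and ``table2`` the 4 enriched KEGG-style
pathways with hypergeometric p, BH FDR and permutation empirical P.
They serve as machine-readable replay fixtures for the integration,
methylation-cutoff and FDR stages.
"""

from __future__ import annotations

import io as _io

import pandas as pd

_TABLE1_TSV = """\
snp	chrom	pos	gene	location	gwas_p	eqtl_p	pfp	fc	histone_marks	probe	meth_p
rs4648881	1	25197155	MTFR1L	5'	5e-07	4.0e-03	2.33e-02	-1.30
rs9633402	1	247946160	TRIM58	5'	3e-06	5.4e-04	1.15e-02	1.21		cg12689806	8.45e-02
rs79893749	3	46253650	CCR3	intron	2e-07	2.5e-04	1.68e-02	-1.27	H3K4me1_Enh	cg04111761	7.78e-03
rs4869313	5	96223880	ELL2	5'	9e-08	2.4e-02	4.04e-02	-1.26
rs41291794	6	32425762	HLA-DPA1	3'	4e-15	1.4e-02	8.20e-04	1.33		cg13906813	1.64e-02
rs7069750	10	90762376	ACTA2	5'	3e-08	4.9e-20	3.60e-03	1.27		cg03111039	6.52e-08
rs7069750	10	90762376	ANKRD22	5'	3e-08	4.0e-03	3.64e-02	1.21		cg15103050	1.52e-01
rs12598357	16	28340945	SH2B1	5'	4e-09	4.4e-06	3.83e-04	1.68		cg07884168	1.55e-02
rs12598357	16	28340945	SULT1A1	3'	4e-09	9.6e-07	5.51e-03	-1.31		cg09685060	1.41e-09
rs12928404	16	28847246	SH2B1	5'	6e-07	1.9e-04	3.83e-04	1.68		cg06932837	5.13e-05
rs12928404	16	28847246	SULT1A1	5'	6e-07	5.0e-06	5.51e-03	-1.31		cg26603685	1.72e-07
rs2847293	18	12782448	MPPE1	5'	1e-12	3.9e-02	2.01e-02	-1.36		cg14599440	2.01e-03
rs149850873	18	12885120	CEP192	5'	5e-07	6.0e-03	4.90e-03	-1.37	H3K4me1_Enh H3K4me3_Pro	cg00686761	1.78e-01
"""

_TABLE2_TSV = """\
pathway	total	expected	hits	p_value	fdr	empirical_p
Neurotrophin signaling pathway	123	1.34	10	5.60e-07	1.21e-04	0.1
Cardiac muscle contraction	12	0.131	4	5.81e-06	6.30e-04	<0.01
Cell cycle	124	1.35	8	4.74e-05	3.43e-03	0.14
Hypertrophic cardiomyopathy	25	0.272	4	1.34e-04	7.25e-03	<0.01
"""

FIXTURE_NAMES = ("table1", "table2")


def table1() -> pd.DataFrame:
    """The 13 SNP-gene target pairs (strings preserved for ids/marks)."""
    df = pd.read_csv(
        _io.StringIO(_TABLE1_TSV),
        sep="\t",
        dtype={"chrom": str},
        keep_default_na=False,
        na_values=[""],
    )
    df["histone_marks"] = df["histone_marks"].fillna("")
    return df


def table2() -> pd.DataFrame:
    """The 4 enriched pathways (empirical_p kept as printed strings)."""
    return pd.read_csv(_io.StringIO(_TABLE2_TSV), sep="\t", dtype={"empirical_p": str})


def fixture(name: str) -> pd.DataFrame:
    if name == "table1":
        return table1()
    if name == "table2":
        return table2()
    raise ValueError(
        f"unknown fixture {name!r}; valid fixtures: {', '.join(FIXTURE_NAMES)}"
    )


def table1_gwas_snps() -> pd.DataFrame:
    """Distinct GWAS SNPs of the case-study table."""
    t = table1()
    return (
        t[["snp", "chrom", "pos", "gwas_p"]]
        .drop_duplicates("snp")
        .reset_index(drop=True)
    )


def table1_eqtl_records() -> pd.DataFrame:
    """SNP-gene eQTL associations (snp, gene, p_value) of the table."""
    t = table1()
    return t[["snp", "gene", "eqtl_p"]].rename(columns={"eqtl_p": "p_value"})


def table1_deg_results() -> pd.DataFrame:
    """Per-gene rank-product results reconstructed from the table.

    The published table prints one PFP per gene with the direction
    implied by the fold-change sign; the reconstruction places that PFP
    on the matching side and a null value (1.0) on the other.
    """
    t = table1().drop_duplicates("gene")
    up = t["fc"] > 0
    return pd.DataFrame(
        {
            "pfp_up": t["pfp"].where(up, 1.0).to_numpy(),
            "pfp_down": t["pfp"].where(~up, 1.0).to_numpy(),
            "fc": t["fc"].to_numpy(),
        },
        index=pd.Index(t["gene"], name="gene"),
    )


def table1_annotations() -> pd.DataFrame:
    """(snp, gene) -> location annotations as printed."""
    return table1()[["snp", "gene", "location"]]


def table1_meth_pvalues() -> pd.Series:
    """The methylation p-values printed in the table (11 of 13 rows)."""
    t = table1().dropna(subset=["probe"])
    return pd.Series(
        t["meth_p"].to_numpy(dtype=float), index=t["probe"], name="meth_p"
    )
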