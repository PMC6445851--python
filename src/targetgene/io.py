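"""Plain-text readers/writers for the pipeline's tabular formats.

Everything is TSV except pathways (GMT) and histone intervals (BED);
expression studies are a genes x samples TSV plus a two-column sample
label TSV.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .expression import ExpressionStudy
from .integration import GenomicInterval


def write_expression_study(study: ExpressionStudy, outdir) -> tuple[Path, Path]:
    outdir = Path(outdir)
    vpath = outdir / f"{study.study_id}_expression.tsv"
    lpath = outdir / f"{study.study_id}_labels.tsv"
    study.values.rename_axis("gene").to_csv(vpath, sep="\t")
    study.labels.rename_axis("sample").to_frame("label").to_csv(
        lpath, sep="\t"
    )
    return vpath, lpath


def read_expression_study(study_id: str, values_path, labels_path) -> ExpressionStudy:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)["label"]
    return ExpressionStudy(study_id, values, labels)


def write_matrix(df: pd.DataFrame, path, index_name: str = "id") -> None:
    df.rename_axis(index_name).to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                chrom, start, end, label = iv.chrom, iv.start, iv.end, iv.label
            else:  # a DataFrame row / mapping
                chrom, start, end, label = (
                    iv["chrom"], iv["start"], iv["end"], iv["label"]
                )
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(
            tuple(sorted((str(u), str(v)))) for u, v in graph.edges
        ):
            fh.write(f"{a}\t{b}\n")


def read_edge_list(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    g.add_edges_from(
        (str(a), str(b))
        for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
        if str(a) != str(b)
    )
    return g
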