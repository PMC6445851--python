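"""Microarray-style expression preprocessing.

Operates on :class:`ExpressionStudy` containers (genes x samples intensity
matrices with case/control labels) and provides the three standard steps
used before differential-expression meta-analysis: log2 transformation for
variance stabilisation, quantile normalisation across arrays (the
normalisation step of RMA), and Tukey median polish for summarising
probe-level values to one value per gene and sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionStudy:
    """One cohort's expression matrix with sample class labels.

    Parameters
    ----------
    study_id : str
        Identifier for the cohort (e.g. a GEO-series-style accession).
    values : pandas.DataFrame
        Genes (rows) x samples (columns). Intensities must be positive
        before log transformation.
    labels : pandas.Series
        Per-sample class label, ``"case"`` or ``"control"``, indexed by
        sample id in the same order as ``values.columns``.
    """

    study_id: str
    values: pd.DataFrame
    labels: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError(f"{self.study_id}: duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError(f"{self.study_id}: duplicate sample ids")
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise ValueError(f"{self.study_id}: samples without labels: {missing}")
        bad = set(self.labels.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"{self.study_id}: unknown labels {sorted(bad)}")

    @property
    def case_samples(self) -> list:
        return list(self.labels.index[self.labels == CASE])

    @property
    def control_samples(self) -> list:
        return list(self.labels.index[self.labels == CONTROL])

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def log2_transform(study: ExpressionStudy) -> ExpressionStudy:
    """Elementwise log2 of the intensity matrix; labels preserved.

    Raises
    ------
    ValueError
        If any value is <= 0; the error names the offending gene and
        sample so the bad cell can be located in the input file.
    """
    vals = study.values
    if (vals.to_numpy() <= 0).any():
        r, c = np.argwhere(vals.to_numpy() <= 0)[0]
        raise ValueError(
            f"{study.study_id}: non-positive intensity "
            f"{vals.iat[r, c]!r} at gene {vals.index[r]!r}, "
            f"sample {vals.columns[c]!r}; log2 undefined"
        )
    return replace(study, values=np.log2(vals))


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Quantile-normalise columns so every array shares one distribution.

    After normalisation each column's sorted values equal the per-rank
    means of the input columns; within-column rank order is preserved.
    Tied values receive the mean of the tied ranks' reference values
    (the value of the reference distribution linearly interpolated at
    the mid-rank), the standard convention.

    A single-column study is returned unchanged with a warning: there is
    nothing to normalise across.
    """
    vals = study.values
    n, m = vals.shape
    if m < 2:
        warnings.warn(
            f"{study.study_id}: quantile normalisation of a single array "
            "is the identity",
            stacklevel=2,
        )
        return replace(study, values=vals.copy())
    arr = vals.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(m):
        ranks = rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return replace(
        study, values=pd.DataFrame(out, index=vals.index, columns=vals.columns)
    )


def median_polish(
    table: pd.DataFrame | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a probe-by-sample matrix.

    Alternately sweeps row then column medians out of the residuals until
    the largest absolute change in any effect is below ``tol`` or
    ``max_iter`` iterations have run, decomposing

        table ~= overall + row_effect[i] + col_effect[j] + residual[i, j]

    with row and column effects having median zero. The per-sample gene
    summary used by RMA-style pipelines is ``overall + col_effect``.

    Returns
    -------
    overall : float
    row_effects : ndarray, shape (n_rows,)
    col_effects : ndarray, shape (n_cols,)
    residuals : ndarray, shape (n_rows, n_cols)
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("median_polish needs a non-empty 2-D matrix")
    resid = arr.copy()
    overall = 0.0
    row = np.zeros(arr.shape[0])
    col = np.zeros(arr.shape[1])
    for _ in range(max_iter):
        delta = 0.0
        # rows swept first (fixed order makes the decomposition deterministic)
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row += rmed
        cmed_of_row = np.median(row)
        row -= cmed_of_row
        overall += cmed_of_row
        delta = max(delta, np.abs(rmed).max(), abs(cmed_of_row))

        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col += cmed
        rmed_of_col = np.median(col)
        col -= rmed_of_col
        overall += rmed_of_col
        delta = max(delta, np.abs(cmed).max(), abs(rmed_of_col))
        if delta < tol:
            break
    return overall, row, col, resid


def summarize_probes(
    study: ExpressionStudy, probe_map: pd.Series, **polish_kwargs
) -> ExpressionStudy:
    """Collapse probe-level rows to gene level via median polish.

    ``probe_map`` maps probe id (index) -> gene id. Probes absent from the
    map are dropped. Each gene's summary per sample is
    ``overall + column effect`` from the polish of its probe block.
    """
    vals = study.values
    probe_map = probe_map.reindex(vals.index).dropna()
    rows = []
    genes = []
    for gene, probes in probe_map.groupby(probe_map).groups.items():
        block = vals.loc[list(probes)]
        overall, _, coleff, _ = median_polish(block, **polish_kwargs)
        rows.append(overall + coleff)
        genes.append(gene)
    summary = pd.DataFrame(rows, index=genes, columns=vals.columns)
    return replace(study, values=summary.sort_index())
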