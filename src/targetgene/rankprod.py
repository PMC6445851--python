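"""Two-class rank-product meta-analysis with permutation PFP.

The rank product of a gene over k case-vs-control comparisons is the
geometric mean of its fold-change ranks,

    RP_g = (prod_c r_{g,c})^(1/k),

small when the gene is consistently near the top (up-regulation) or
bottom (down-regulation) of every comparison. Significance is attached
by the percentage-of-false-positives (PFP) statistic: rank vectors are
permuted within each comparison B times, the expected number of null
genes with RP at least as extreme as each observed RP is estimated, and
PFP(g) = E[false positives at RP_g] / rank(g by observed RP). PFP
estimates the false discovery rate of the list cut at gene g.

Comparisons are formed per study as case x control sample pairs (all of
them, or a seeded random subset when the product is large) and pooled
across studies with study-of-origin labels; permutation is always within
a comparison, never across studies, preserving study structure under the
null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import ExpressionStudy

UP = "up"
DOWN = "down"
NS = "ns"

DEFAULT_PAIR_CAP = 50


@dataclass
class Comparison:
    """One case-vs-control contrast: per-gene log2 fold change."""

    study_id: str
    case: str
    control: str
    log2_fc: pd.Series = field(repr=False)


def pairwise_comparisons(
    studies: list[ExpressionStudy],
    cap: int | None = DEFAULT_PAIR_CAP,
    seed: int | None = None,
    scheme: str = "all_pairs",
) -> list[Comparison]:
    """Build case x control log2 fold-change vectors per study.

    Studies are assumed to hold log2-scale values (the pipeline applies
    :func:`targetgene.expression.log2_transform` first), so a comparison
    is simply ``case column - control column``.

    Parameters
    ----------
    cap : int or None
        Maximum number of pairs per study. When the available pairs
        exceed ``cap``, a seeded uniform subset of that size is used.
        ``None`` means no cap.
    seed : int, optional
        Seed for pair selection; required for reproducibility whenever
        the selection is random.
    scheme : {"all_pairs", "disjoint"}
        ``"all_pairs"`` enumerates every case x control pair. Pairs
        then share samples, so fold-change vectors are positively
        correlated across comparisons — which the independent
        within-comparison permutation null of :func:`estimate_pfp`
        does not model, making PFP anti-conservative. ``"disjoint"``
        (the :class:`RankProduct` default) draws a seeded random
        pairing in which each sample is used at most once per study
        (k = min(cases, controls, cap) comparisons), keeping
        comparisons independent under the null.
    """
    if scheme not in ("all_pairs", "disjoint"):
        raise ValueError(f"unknown comparison scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    comparisons: list[Comparison] = []
    for study in studies:
        cases = study.case_samples
        controls = study.control_samples
        if not cases or not controls:
            raise ValueError(
                f"{study.study_id}: needs at least one case and one control "
                f"(got {len(cases)} cases, {len(controls)} controls)"
            )
        if scheme == "all_pairs":
            pairs = [(a, b) for a in cases for b in controls]
            if cap is not None and len(pairs) > cap:
                idx = rng.choice(len(pairs), size=cap, replace=False)
                pairs = [pairs[i] for i in sorted(idx)]
        else:
            k = min(len(cases), len(controls))
            if cap is not None:
                k = min(k, cap)
            case_idx = rng.permutation(len(cases))[:k]
            control_idx = rng.permutation(len(controls))[:k]
            pairs = [
                (cases[i], controls[j])
                for i, j in zip(case_idx, control_idx)
            ]
        vals = study.values
        for a, b in pairs:
            comparisons.append(
                Comparison(study.study_id, a, b, vals[a] - vals[b])
            )
    return comparisons


def _fc_matrix(comparisons: list[Comparison]) -> tuple[np.ndarray, pd.Index]:
    genes = comparisons[0].log2_fc.index
    for c in comparisons[1:]:
        if not c.log2_fc.index.equals(genes):
            raise ValueError(
                f"comparison {c.study_id}:{c.case}-{c.control} covers a "
                "different gene set"
            )
    return np.vstack([c.log2_fc.to_numpy() for c in comparisons]), genes


def comparison_ranks(comparisons: list[Comparison], direction: str) -> np.ndarray:
    """Within-comparison fold-change ranks, shape (k, n_genes).

    Rank 1 is the largest fold change for ``direction="up"`` and the
    smallest for ``"down"``; ties receive mid-ranks.
    """
    if not comparisons:
        raise ValueError("need at least one comparison")
    if direction not in (UP, DOWN):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    fc, _ = _fc_matrix(comparisons)
    signed = -fc if direction == UP else fc
    return rankdata(signed, axis=1, method="average")


def rank_product(comparisons: list[Comparison], direction: str) -> pd.Series:
    """Per-gene rank product RP = (prod of ranks)^(1/k)."""
    ranks = comparison_ranks(comparisons, direction)
    _, genes = _fc_matrix(comparisons)
    rp = np.exp(np.mean(np.log(ranks), axis=0))
    return pd.Series(rp, index=genes, name=f"rp_{direction}")


def estimate_pfp(
    observed_rp: pd.Series,
    ranks: np.ndarray,
    b: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation PFP for each gene's observed rank product.

    For each of ``b`` rounds the observed rank vector of every comparison
    is independently and uniformly permuted (preserving the tie
    structure), null rank products are computed for all genes, and the
    expected number of null genes with RP <= RP_g is estimated as
    E[x](g) = (total count across rounds) / b. Then

        PFP(g) = E[x](g) / rank of g by observed RP (ascending).

    Returns a DataFrame with columns ``pfp`` (raw, not truncated at 1)
    and ``pfp_monotone`` (step-down cumulative minimum over genes ordered
    by ascending RP, which makes PFP non-decreasing in RP).
    """
    if b < 1:
        raise ValueError("number of permutation rounds b must be >= 1")
    rng = np.random.default_rng(seed)
    obs = observed_rp.to_numpy(dtype=float)
    n = obs.size
    obs_log = np.log(obs)
    null_logs = np.empty((b, n))
    for i in range(b):
        perm = rng.permuted(ranks, axis=1)
        null_logs[i] = np.mean(np.log(perm), axis=0)
    flat = np.sort(null_logs.ravel())
    # count null RP <= observed RP; tiny slack absorbs log-space round-off
    counts = np.searchsorted(flat, obs_log + 1e-9, side="right")
    ex = counts / b
    obs_rank = rankdata(obs, method="max")
    pfp = ex / obs_rank
    order = np.argsort(obs, kind="stable")
    mono = np.empty(n)
    mono[order] = np.minimum.accumulate(pfp[order][::-1])[::-1]
    return pd.DataFrame(
        {"pfp": pfp, "pfp_monotone": mono, "expected_fp": ex},
        index=observed_rp.index,
    )


def signed_fold_change(studies: list[ExpressionStudy]) -> pd.Series:
    """Signed case/control fold change pooled across studies.

    Per study the log2 ratio of case to control geometric means is taken
    (equivalently, difference of class means on the log2 scale); studies
    are pooled by the unweighted mean of per-study log2 ratios. The ratio
    r = 2^pooled is reported as r when r >= 1 and -1/r otherwise, so the
    threshold |FC| > 1.2 is symmetric in both directions. r = 1 maps to
    +1.0 by convention.
    """
    if not studies:
        raise ValueError("need at least one study")
    per_study = []
    for study in studies:
        vals = study.values
        log2_ratio = vals[study.case_samples].mean(axis=1) - vals[
            study.control_samples
        ].mean(axis=1)
        per_study.append(log2_ratio)
    pooled = pd.concat(per_study, axis=1).mean(axis=1)
    if pooled.isna().any():
        missing = pooled.index[pooled.isna()].tolist()
        raise ValueError(f"genes absent from every study: {missing}")
    r = np.power(2.0, pooled)
    fc = np.where(r >= 1.0, r, -1.0 / r)
    return pd.Series(fc, index=pooled.index, name="fc")


def filter_degs(
    results: pd.DataFrame, pfp_max: float = 0.05, fc_min: float = 1.2
) -> pd.DataFrame:
    """Call differentially expressed genes.

    Keeps genes with min(PFP_up, PFP_down) < ``pfp_max`` (strict) and
    |FC| > ``fc_min`` (strict); direction comes from the smaller-PFP
    side. Expects the frame produced by :meth:`RankProductResults.table`.
    """
    if pfp_max <= 0 or fc_min <= 0:
        raise ValueError("thresholds must be positive")
    best_pfp = results[["pfp_up", "pfp_down"]].min(axis=1)
    keep = (best_pfp < pfp_max) & (results["fc"].abs() > fc_min)
    out = results.loc[keep].copy()
    out["direction"] = np.where(out["pfp_up"] <= out["pfp_down"], UP, DOWN)
    return out


class RankProduct:
    """Rank-product meta-analysis model over one or more cohorts.

    Parameters
    ----------
    studies : list of ExpressionStudy
        Log2-scale, normalised expression studies sharing a gene index.
    cap : int or None
        Per-study cap on case x control pairs (seeded subset beyond it).
    seed : int, optional
        Master seed; pair subsetting and the PFP permutations draw
        dedicated substreams from it.
    scheme : {"disjoint", "all_pairs"}
        Comparison scheme (see :func:`pairwise_comparisons`); the
        default disjoint pairing keeps comparisons independent so the
        permutation PFP is calibrated.

    Examples
    --------
    >>> model = RankProduct(studies, seed=7)
    >>> res = model.fit(b=100)
    >>> degs = res.filter_degs(pfp_max=0.05, fc_min=1.2)
    """

    def __init__(
        self,
        studies: list[ExpressionStudy],
        cap: int | None = DEFAULT_PAIR_CAP,
        seed: int | None = None,
        scheme: str = "disjoint",
    ):
        self.studies = studies
        self.seed = seed
        self.scheme = scheme
        ss = np.random.SeedSequence(seed)
        pair_seed, pfp_up_seed, pfp_down_seed = ss.spawn(3)
        self._pfp_seeds = (pfp_up_seed, pfp_down_seed)
        self.comparisons = pairwise_comparisons(
            studies, cap=cap, seed=pair_seed, scheme=scheme
        )

    @property
    def n_comparisons(self) -> int:
        return len(self.comparisons)

    def fit(self, b: int = 100) -> "RankProductResults":
        """Run the meta-analysis with ``b`` permutation rounds."""
        rows = {}
        for direction, pfp_seed in zip((UP, DOWN), self._pfp_seeds):
            ranks = comparison_ranks(self.comparisons, direction)
            rp = rank_product(self.comparisons, direction)
            pfp = estimate_pfp(rp, ranks, b=b, seed=pfp_seed)
            rows[f"rp_{direction}"] = rp
            rows[f"pfp_{direction}"] = pfp["pfp"]
            rows[f"pfp_{direction}_monotone"] = pfp["pfp_monotone"]
        table = pd.DataFrame(rows)
        table["fc"] = signed_fold_change(self.studies)
        return RankProductResults(self, table, b)


class RankProductResults:
    """Fitted rank-product results: RP, PFP and signed FC per gene."""

    def __init__(self, model: RankProduct, table: pd.DataFrame, b: int):
        self.model = model
        self._table = table
        self.b = b

    def table(self) -> pd.DataFrame:
        """Per-gene results frame (copy)."""
        return self._table.copy()

    def filter_degs(
        self, pfp_max: float = 0.05, fc_min: float = 1.2
    ) -> pd.DataFrame:
        return filter_degs(self._table, pfp_max=pfp_max, fc_min=fc_min)

    def summary(self) -> str:
        t = self._table
        degs = self.filter_degs()
        n_up = int((degs["direction"] == UP).sum())
        n_down = int((degs["direction"] == DOWN).sum())
        lines = [
            "Rank-product meta-analysis",
            "==========================",
            f"studies:             {len(self.model.studies)}",
            f"genes:               {len(t)}",
            f"comparisons (k):     {self.model.n_comparisons}",
            f"permutation rounds:  {self.b}",
            f"DEGs (PFP<0.05, |FC|>1.2): {len(degs)} "
            f"({n_up} up, {n_down} down)",
        ]
        return "\n".join(lines)
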