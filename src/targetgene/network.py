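"""First-order PPI subnetworks, hypergeometric pathway enrichment,
BH FDR and permutation-derived empirical pathway p-values.

The enrichment universe defaults to the genes that are both present in
the interactome and carry at least one pathway annotation, so observed
and resampled gene lists are judged against the same background. For a
pathway with ``Total`` annotated genes, a network covering ``draws``
universe genes and ``Hits`` of the pathway's genes, the enrichment
p-value is the upper hypergeometric tail P(X >= Hits) and
``Expected = Total * draws / |universe|``.

The empirical pathway p-value repeats the whole chain — seed list ->
first-order network -> hypergeometric enrichment -> BH FDR < 0.05 — for
R random seed lists of the same size and reports the fraction of
resamples in which the pathway recurs as significant; a pathway that
never recurs is reported as "<1/R".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class PathwayDB:
    """Named gene sets plus the background universe they live in."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, genes in self.sets.items() if not genes]
        if empty:
            raise ValueError(f"empty pathway sets: {empty}")

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out

    def restrict(self, universe: set[str]) -> "PathwayDB":
        """Intersect every set with ``universe``, dropping emptied sets."""
        sets = {
            name: genes & universe
            for name, genes in self.sets.items()
            if genes & universe
        }
        return PathwayDB(sets, self.descriptions)


def read_gmt(path) -> PathwayDB:
    sets, desc = {}, {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
            desc[parts[0]] = parts[1]
    return PathwayDB(sets, desc)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for name in db.sets:
            genes = "\t".join(sorted(db.sets[name]))
            fh.write(f"{name}\t{db.descriptions.get(name, '')}\t{genes}\n")


def first_order_network(
    interactome: nx.Graph, seeds: set[str]
) -> tuple[nx.Graph, dict[str, str], list[str]]:
    """Subgraph induced by present seeds plus their direct interactors.

    Returns the subgraph, a node -> role mapping ("seed" or
    "interactor"), and the list of seeds absent from the interactome
    (reported, never silently dropped). Present seeds with no
    interactions are retained as isolated nodes.
    """
    if not seeds:
        raise ValueError("seed gene list is empty")
    present = sorted(s for s in seeds if s in interactome)
    missing = sorted(s for s in seeds if s not in interactome)
    nodes = set(present)
    for s in present:
        nodes |= set(interactome.neighbors(s))
    sub = interactome.subgraph(nodes).copy()
    roles = {
        n: ("seed" if n in set(present) else "interactor") for n in sub.nodes
    }
    return sub, roles, missing


def hypergeom_enrich(
    network_genes: set[str],
    pathways: PathwayDB,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each pathway.

    ``universe`` defaults to the union of all pathway genes; pathway
    sets must lie inside it. Network genes are intersected with the
    universe before testing. Output columns: pathway, total, expected,
    hits, p_value.
    """
    if universe is None:
        universe = pathways.genes
    outside = {
        name: sorted(genes - universe)
        for name, genes in pathways.sets.items()
        if genes - universe
    }
    if outside:
        raise ValueError(
            f"pathway genes outside the universe: {outside}"
        )
    n_universe = len(universe)
    draws = len(network_genes & universe)
    rows = []
    for name, genes in pathways.sets.items():
        total = len(genes)
        hits = len(network_genes & genes)
        p = float(hypergeom.sf(hits - 1, n_universe, total, draws))
        rows.append(
            {
                "pathway": name,
                "total": total,
                "expected": total * draws / n_universe,
                "hits": hits,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def bh_fdr(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    ``m`` is the total number of tests (>= len(pvalues)); passing a
    larger m supports adjusting a printed subset of a bigger family.
    adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than the number of p-values {p.size}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out


def empirical_pathway_pvalues(
    interactome: nx.Graph,
    pathways: PathwayDB,
    observed_pathways: list[str],
    list_size: int,
    r: int = 100,
    seed: int | None = None,
    universe: set[str] | None = None,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Permutation empirical p-value for each observed pathway.

    Draws ``r`` random gene lists of ``list_size`` (without replacement,
    from the enrichment universe), reruns first-order network ->
    hypergeometric enrichment -> BH FDR for each, and counts per pathway
    the resamples in which it reaches FDR < ``fdr_max``. Empirical
    P = b / r, rendered "<1/r" (e.g. "<0.01" at r=100) when b = 0.

    Output columns: pathway, b, empirical_p, empirical_p_display.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if universe is None:
        universe = pathways.genes
    pool = sorted(universe)
    if list_size > len(pool):
        raise ValueError(
            f"list_size {list_size} exceeds universe size {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    counts = {name: 0 for name in observed_pathways}
    for _ in range(r):
        random_seeds = set(
            rng.choice(pool, size=list_size, replace=False).tolist()
        )
        sub, _, _ = first_order_network(interactome, random_seeds)
        enr = hypergeom_enrich(set(sub.nodes), pathways, universe=universe)
        enr["fdr"] = bh_fdr(enr["p_value"].to_numpy())
        flagged = set(enr.loc[enr["fdr"] < fdr_max, "pathway"])
        for name in counts:
            if name in flagged:
                counts[name] += 1
    rows = []
    floor_display = np.format_float_positional(
        1.0 / r, trim="-", fractional=True
    )
    for name in observed_pathways:
        b = counts[name]
        rows.append(
            {
                "pathway": name,
                "b": b,
                "empirical_p": b / r,
                "empirical_p_display": (
                    f"<{floor_display}" if b == 0
                    else np.format_float_positional(b / r, trim="-")
                ),
            }
        )
    return pd.DataFrame(rows)


class NetworkEnrichment:
    """Pathway enrichment model for a seed gene list on an interactome.

    fit() builds the first-order network, computes hypergeometric
    enrichment with BH FDR over all tested pathways, and (optionally)
    the permutation empirical p-values of the significant pathways.
    """

    def __init__(
        self,
        interactome: nx.Graph,
        pathways: PathwayDB,
        seeds: set[str],
        universe: set[str] | None = None,
    ):
        self.interactome = interactome
        self.seeds = set(seeds)
        if universe is None:
            # genes both in the interactome and pathway-annotated
            universe = pathways.genes & set(interactome.nodes)
        self.universe = set(universe)
        self.pathways = pathways.restrict(self.universe)

    def fit(
        self,
        fdr_max: float = 0.05,
        r: int | None = 100,
        seed: int | None = None,
    ) -> "EnrichmentResults":
        sub, roles, missing = first_order_network(self.interactome, self.seeds)
        enr = hypergeom_enrich(
            set(sub.nodes), self.pathways, universe=self.universe
        )
        enr["fdr"] = bh_fdr(enr["p_value"].to_numpy())
        enr = enr.sort_values("p_value", kind="stable").reset_index(drop=True)
        significant = enr.loc[enr["fdr"] < fdr_max, "pathway"].tolist()
        if r is not None and significant:
            emp = empirical_pathway_pvalues(
                self.interactome,
                self.pathways,
                significant,
                list_size=len(self.seeds),
                r=r,
                seed=seed,
                universe=self.universe,
                fdr_max=fdr_max,
            )
            enr = enr.merge(emp, on="pathway", how="left")
        else:
            enr["b"] = pd.NA
            enr["empirical_p"] = np.nan
            enr["empirical_p_display"] = pd.NA
        return EnrichmentResults(self, sub, roles, missing, enr, fdr_max)


class EnrichmentResults:
    def __init__(self, model, subgraph, roles, missing_seeds, table, fdr_max):
        self.model = model
        self.subgraph = subgraph
        self.roles = roles
        self.missing_seeds = missing_seeds
        self._table = table
        self.fdr_max = fdr_max

    def table(self) -> pd.DataFrame:
        return self._table.copy()

    @property
    def significant(self) -> pd.DataFrame:
        t = self._table
        return t.loc[t["fdr"] < self.fdr_max].copy()

    def summary(self) -> str:
        lines = [
            "First-order network pathway enrichment",
            "======================================",
            f"seeds:            {len(self.model.seeds)} "
            f"({len(self.missing_seeds)} absent from interactome)",
            f"network nodes:    {self.subgraph.number_of_nodes()}",
            f"network edges:    {self.subgraph.number_of_edges()}",
            f"universe size:    {len(self.model.universe)}",
            f"pathways tested:  {len(self._table)}",
            f"FDR < {self.fdr_max}:       {len(self.significant)}",
        ]
        return "\n".join(lines)
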