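"""Gene-impact ranking and quality-control efficiency.

Edge scores are summed over every tumour in the cohort and credited in
full to both endpoint genes; per-gene totals rank the most impactful
losses (lowest totals) and gains (highest totals). The QC efficiency of a
set of per-pathway top-k tables against a reference driver-gene list is
the percentage of possible hits (reference genes inside the eligible
universe) actually recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ConfigurationError, CopyNumberMatrix
from .network import DEFAULT_SCORER, CompiledModule, EdgeScorer, PathwayNetwork

__all__ = [
    "GeneImpactTable",
    "QCReport",
    "gene_impact_scores",
    "top_impact_genes",
    "qc_efficiency",
]


@dataclass
class GeneImpactTable:
    """Per-gene summed edge-score credit across the whole cohort.

    ``frame`` columns: gene, score, rank_loss, rank_gain, gds,
    n_incident_edges. Ranks are 1-based permutations; ties broken by
    |score| descending then gene symbol ascending.
    """

    pathway: str
    frame: pd.DataFrame
    scorer: str = "default"
    normalized: bool = False

    def score(self, gene: str) -> float:
        row = self.frame.loc[self.frame["gene"] == gene, "score"]
        if row.empty:
            raise KeyError(gene)
        return float(row.iloc[0])

    @property
    def total(self) -> float:
        return float(self.frame["score"].sum())


def _assign_ranks(df: pd.DataFrame) -> pd.DataFrame:
    # loss rank: most negative first; gain rank: most positive first.
    # Ties: |score| descending, then symbol ascending (deterministic).
    loss_order = df.sort_values(
        by=["score", "abs_score", "gene"], ascending=[True, False, True],
        kind="stable").index
    gain_order = df.sort_values(
        by=["score", "abs_score", "gene"], ascending=[False, False, True],
        kind="stable").index
    df.loc[loss_order, "rank_loss"] = np.arange(1, len(df) + 1)
    df.loc[gain_order, "rank_gain"] = np.arange(1, len(df) + 1)
    df["rank_loss"] = df["rank_loss"].astype(int)
    df["rank_gain"] = df["rank_gain"].astype(int)
    return df


def gene_impact_scores(network: PathwayNetwork, matrix: CopyNumberMatrix,
                       scorer: EdgeScorer = DEFAULT_SCORER,
                       normalized: bool = False) -> GeneImpactTable:
    """Credit every edge's per-sample score to both endpoints and rank genes.

    By default raw edge scores are summed over all samples; with
    ``normalized=True`` each edge's contribution is divided by the
    module's |minimum haploinsufficient score| first.
    """
    if not network.scorable:
        raise ConfigurationError(f"network {network.name!r} is unscorable")
    if matrix.mode != "discrete":
        raise ConfigurationError("impact scoring requires a discrete matrix")
    compiled = CompiledModule(network, matrix.genes, scorer)
    values = matrix.values.to_numpy()
    padded = np.vstack([values, np.zeros((1, values.shape[1]), dtype=values.dtype)])
    c1 = padded[compiled._i1]
    c2 = padded[compiled._i2]
    edge_scores = scorer.score_arrays(c1, c2, compiled._w1[:, None], compiled._w2[:, None])
    per_edge = edge_scores.sum(axis=1)  # summed over tumours
    if normalized and compiled.min_score != 0:
        per_edge = per_edge / abs(compiled.min_score)
    totals: dict[str, float] = {g: 0.0 for g in network.nodes}
    n_incident: dict[str, int] = {g: 0 for g in network.nodes}
    for (a, b), s in zip(network.edges, per_edge):
        totals[a] += s
        totals[b] += s
        n_incident[a] += 1
        n_incident[b] += 1
    genes = sorted(network.nodes)
    df = pd.DataFrame({
        "gene": genes,
        "score": [totals[g] for g in genes],
        "gds": [network.gds[g] for g in genes],
        "n_incident_edges": [n_incident[g] for g in genes],
    })
    df["abs_score"] = df["score"].abs()
    df = _assign_ranks(df).drop(columns="abs_score")
    df = df[["gene", "score", "rank_loss", "rank_gain", "gds", "n_incident_edges"]]
    return GeneImpactTable(pathway=network.name, frame=df.reset_index(drop=True),
                           scorer=scorer.name, normalized=normalized)


def top_impact_genes(table: GeneImpactTable, k: int, direction: str = "loss") -> list[str]:
    """First k genes by loss rank (lowest scores) or gain rank (highest)."""
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if direction not in ("loss", "gain"):
        raise ConfigurationError(f"direction must be 'loss' or 'gain', got {direction!r}")
    col = "rank_loss" if direction == "loss" else "rank_gain"
    ordered = table.frame.sort_values(col, kind="stable")
    return list(ordered["gene"].head(k))


@dataclass
class QCReport:
    """Recovery of a reference driver-gene set by the top-k impact tables."""

    efficiency: float               # 100 * found / possible_hits
    possible_hits: int              # |reference & universe|
    found: int                      # |reference & union of top tables|
    k: int
    n_tables: int
    degenerate: bool = False        # reference disjoint from universe
    table_capacity_efficiency: float | None = None  # alternative denominator

    def __post_init__(self) -> None:
        if not (0.0 <= self.efficiency <= 100.0):
            raise ValueError("efficiency outside [0, 100]")


def qc_efficiency(top_tables: Mapping[str, Sequence[str]], reference: Iterable[str],
                  universe: Iterable[str], k: int | None = None) -> QCReport:
    """Percentage of possible reference hits present in the top tables.

    ``universe`` is the set of genes eligible to appear in any top table;
    ``possible_hits = |reference & universe|``. When the total table
    capacity is smaller than the possible hits, the capacity-denominator
    alternative is reported alongside.
    """
    ref = {g.strip().upper() for g in reference}
    uni = {g.strip().upper() for g in universe}
    table_genes: set[str] = set()
    max_k = 0
    for genes in top_tables.values():
        table_genes.update(g.strip().upper() for g in genes)
        max_k = max(max_k, len(genes))
    possible = len(ref & uni)
    found = len(ref & table_genes)
    if possible == 0:
        return QCReport(efficiency=0.0, possible_hits=0, found=found,
                        k=k if k is not None else max_k,
                        n_tables=len(top_tables), degenerate=True)
    efficiency = 100.0 * found / possible
    capacity = sum(len(genes) for genes in top_tables.values())
    cap_eff = None
    if capacity < possible and capacity > 0:
        cap_eff = 100.0 * found / capacity
    return QCReport(efficiency=efficiency, possible_hits=possible, found=found,
                    k=k if k is not None else max_k, n_tables=len(top_tables),
                    table_capacity_efficiency=cap_eff)
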