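"""Pathway-protein frequency count matrix (PPFCM).

Rows are pathways, columns are dose groups; each cell counts the dose's
differentially expressed genes (after mapping into the pathway namespace)
that are members of the pathway.  An ALL column aggregates across doses and
drives the descending ranking used to pick the top pathways for network
construction.  This is a raw frequency count — no enrichment statistic is
computed, by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .pathways import GeneMapping, PathwayDB, map_genes
from .sam import DEGSet

AGGREGATIONS = ("sum_of_counts", "union_count")


@dataclass
class PPFCM:
    """Counts plus ranking metadata.

    Attributes
    ----------
    counts : DataFrame, pathways × doses, nonnegative integers, ordered by
        rank once :func:`rank_pathways` has run.
    all_column : Series, per-pathway aggregate used for ranking.
    rank : Series, 1-based dense rank (descending all_column, ties broken
        by pathway id).
    aggregation : which aggregation produced ``all_column``.
    """

    counts: pd.DataFrame
    all_column: pd.Series | None = None
    rank: pd.Series | None = None
    aggregation: str | None = None

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def dose_labels(self) -> list[str]:
        return list(self.counts.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        if self.all_column is not None:
            out["ALL"] = self.all_column
        return out

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index_label="pathway_id")
        return path


def build_ppfcm(
    deg_sets: list[DEGSet],
    db: PathwayDB,
    mapping: GeneMapping | None = None,
    policy: str = "expand",
) -> PPFCM:
    """Count each dose's mapped DEGs inside every pathway.

    ``counts[p, d] = |map(DEGs_d) ∩ members(p)|``.  Pathways hit by no DEG
    at any dose keep their all-zero rows (they rank last), so the matrix
    dimension matches the ingested database.
    """
    if not deg_sets:
        raise ValueError("need at least one DEG set")
    doses = [d.dose for d in deg_sets]
    if len(set(doses)) != len(doses):
        raise ValueError(f"dose label collision in {doses}")
    mapped: dict[str, frozenset] = {}
    for ds in deg_sets:
        mapped[ds.dose], _ = map_genes(ds.gene_ids, mapping, policy=policy)
    counts = pd.DataFrame(
        {
            dose: [len(db.members(p) & mapped[dose]) for p in db.pathway_ids]
            for dose in doses
        },
        index=pd.Index(db.pathway_ids, name="pathway_id"),
    )
    m = PPFCM(counts=counts)
    m._mapped_degs = mapped  # kept for union_count aggregation
    return m


def rank_pathways(m: PPFCM, db: PathwayDB | None = None, aggregation: str = "sum_of_counts") -> PPFCM:
    """Attach the ALL column and order rows by descending aggregate.

    ``sum_of_counts`` sums the per-dose cells (the literal "sum of DEGs at
    ALL doses"); ``union_count`` counts the distinct genes a pathway shares
    with the union of all doses' DEGs and needs ``db`` plus the mapped DEG
    sets recorded by :func:`build_ppfcm`.  Ties break lexicographically by
    pathway id, so ranking is deterministic.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}; choose from {AGGREGATIONS}")
    if aggregation == "sum_of_counts":
        all_col = m.counts.sum(axis=1)
    else:
        mapped = getattr(m, "_mapped_degs", None)
        if mapped is None or db is None:
            raise ValueError("union_count needs the PathwayDB and a matrix from build_ppfcm")
        union: frozenset = frozenset().union(*mapped.values())
        all_col = pd.Series(
            [len(db.members(p) & union) for p in m.counts.index], index=m.counts.index
        )
    order = sorted(m.counts.index, key=lambda p: (-int(all_col[p]), p))
    counts = m.counts.loc[order]
    all_col = all_col.loc[order]
    rank = pd.Series(range(1, len(order) + 1), index=counts.index, name="rank")
    out = PPFCM(counts=counts, all_column=all_col, rank=rank, aggregation=aggregation)
    out._mapped_degs = getattr(m, "_mapped_degs", None)
    return out


def top_n(m: PPFCM, n: int = 20) -> PPFCM:
    """Restrict to the ``min(n, rows)`` top-ranked pathways."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if m.rank is None:
        raise ValueError("rank_pathways must run before top_n")
    keep = m.counts.index[:n]
    out = PPFCM(
        counts=m.counts.loc[keep],
        all_column=m.all_column.loc[keep],
        rank=m.rank.loc[keep],
        aggregation=m.aggregation,
    )
    out._mapped_degs = getattr(m, "_mapped_degs", None)
    return out
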