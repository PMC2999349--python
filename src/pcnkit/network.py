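"""Pathway-connected (merging) network over the top-ranked pathways.

Nodes are pathways, sized by membership and colourable by how many of the
active dose's DEGs they contain; an edge joins two pathways when they share
enough members.  The default similarity is the overlap coefficient

    S_ij = |P_i ∩ P_j| / min(|P_i|, |P_j|),

with Jaccard |∩|/|∪| available behind a flag, and the default threshold
rule keeps a pair when S_ij ≥ 0.2 and the pathways share at least 2
members.  Similarity is computed on full pathway membership; DEGs only
affect node attributes.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .pathways import GeneMapping, PathwayDB, map_genes
from .ppfcm import PPFCM
from .sam import DEGSet

SIMILARITIES = ("overlap", "jaccard")
EXPORT_FORMATS = ("graphml", "sif", "edge_table")


def pathway_similarity(
    members_i: frozenset, members_j: frozenset, kind: str = "overlap"
) -> tuple[float, int]:
    """Similarity score and shared-member count for one pathway pair.

    Symmetric, in [0, 1]; 1 exactly when (overlap) the smaller set is
    contained in the larger, or (jaccard) the sets are equal.
    """
    if not members_i or not members_j:
        raise ValueError("pathway member sets must be non-empty")
    if kind not in SIMILARITIES:
        raise ValueError(f"unknown similarity {kind!r}")
    shared = len(frozenset(members_i) & frozenset(members_j))
    if kind == "overlap":
        denom = min(len(members_i), len(members_j))
    else:
        denom = len(frozenset(members_i) | frozenset(members_j))
    return shared / denom, shared


def passes_threshold(
    similarity: float,
    shared_count: int,
    min_similarity: float = 0.2,
    min_shared: int = 2,
) -> bool:
    """Edge rule: similarity ≥ ``min_similarity`` AND at least
    ``min_shared`` shared members."""
    return similarity >= min_similarity and shared_count >= min_shared


def build_network(
    top: PPFCM,
    db: PathwayDB,
    deg_set: DEGSet,
    mapping: GeneMapping | None = None,
    min_similarity: float = 0.2,
    min_shared: int = 2,
    similarity: str = "overlap",
    policy: str = "expand",
) -> nx.Graph:
    """Build the network for one dose over the top-ranked pathways.

    Every top pathway becomes a node (isolates included) with attributes
    ``pathway_size`` and ``deg_count`` (= the PPFCM cell for this dose);
    each unordered pair passing the threshold becomes an edge with
    ``similarity``, ``shared_count`` and the sorted ``shared_members``.
    """
    ids = top.pathway_ids
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate pathway ids")
    if not ids:
        raise ValueError("no pathways to connect")
    mapped, _ = map_genes(deg_set.gene_ids, mapping, policy=policy)

    g = nx.Graph()
    g.graph["dose"] = deg_set.dose
    g.graph["similarity"] = similarity
    g.graph["min_similarity"] = min_similarity
    g.graph["min_shared"] = min_shared
    for p in ids:
        members = db.members(p)
        g.add_node(p, pathway_size=len(members), deg_count=len(members & mapped))
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            mi, mj = db.members(ids[a]), db.members(ids[b])
            score, shared = pathway_similarity(mi, mj, kind=similarity)
            if passes_threshold(score, shared, min_similarity, min_shared):
                g.add_edge(
                    ids[a],
                    ids[b],
                    similarity=float(score),
                    shared_count=int(shared),
                    shared_members=";".join(sorted(mi & mj)),
                )
    return g


def export_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> Path:
    """Write the network as GraphML (all attributes), SIF (relation
    ``overlaps``, isolates listed alone) or a tab-separated edge table."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(net.edges()):
                fh.write(f"{u}\toverlaps\t{v}\n")
            for n in sorted(net.nodes()):
                if net.degree(n) == 0:
                    fh.write(f"{n}\n")
    elif format == "edge_table":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tsimilarity\tshared_count\tshared_members\n")
            for u, v, attrs in sorted(net.edges(data=True)):
                fh.write(
                    f"{u}\t{v}\t{attrs['similarity']}\t{attrs['shared_count']}\t"
                    f"{attrs['shared_members']}\n"
                )
    else:
        raise ValueError(f"unknown export format {format!r}; choose from {EXPORT_FORMATS}")
    return path


def read_graphml(path: str | Path) -> nx.Graph:
    """Re-import a GraphML export (inverse of :func:`export_network`)."""
    return nx.read_graphml(Path(path))
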