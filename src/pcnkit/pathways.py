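"""Gene-set (pathway) ingestion, GMT I/O and cross-namespace symbol mapping.

Pathways are plain membership sets; no topology is kept because the
downstream frequency-count and overlap-similarity computations use set
algebra only.  Member symbols are uppercased at ingest so that comparisons
across namespaces (e.g. rat title-case vs human uppercase symbols) are
case-insensitive by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    source: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id} has no members")
        object.__setattr__(
            self, "members", frozenset(str(m).upper() for m in self.members)
        )

    @property
    def size(self) -> int:
        return len(self.members)


class PathwayDB:
    """A collection of named gene sets with unique pathway ids."""

    def __init__(self, pathways) -> None:
        self._pathways: dict[str, Pathway] = {}
        for p in pathways:
            if p.pathway_id in self._pathways:
                raise ValueError(f"duplicate pathway id {p.pathway_id}")
            self._pathways[p.pathway_id] = p
        if not self._pathways:
            raise ValueError("empty pathway database")

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self):
        return iter(self._pathways.values())

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._pathways

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._pathways[pathway_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayDB):
            return NotImplemented
        return self._pathways == other._pathways

    @property
    def pathway_ids(self) -> list[str]:
        return list(self._pathways)

    def members(self, pathway_id: str) -> frozenset:
        return self._pathways[pathway_id].members

    @property
    def universe(self) -> frozenset:
        """Union of all members (reporting only; no universe statistics)."""
        out: set = set()
        for p in self._pathways.values():
            out |= p.members
        return frozenset(out)


def read_gmt(path: str | Path, source: str | None = None) -> PathwayDB:
    """Read a Broad-dialect GMT file (name TAB description TAB members...).

    Duplicate members within a line are deduplicated with a warning;
    duplicate pathway names are disambiguated by suffixing ``.2``, ``.3``...
    """
    path = Path(path)
    pathways: list[Pathway] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: malformed GMT line (needs ≥3 tab-separated fields, "
                f"got {len(fields)})"
            )
        name, desc, raw_members = fields[0], fields[1], [f for f in fields[2:] if f]
        members = frozenset(m.upper() for m in raw_members)
        if len(members) < len(raw_members):
            logger.warning("%s:%d: duplicate members in %r deduplicated", path, lineno, name)
        pid = name
        if name in seen:
            seen[name] += 1
            pid = f"{name}.{seen[name]}"
            logger.warning("%s:%d: duplicate pathway name %r renamed to %r", path, lineno, name, pid)
        else:
            seen[name] = 1
        pathways.append(
            Pathway(pathway_id=pid, name=name, source=source or desc or path.stem, members=members)
        )
    return PathwayDB(pathways)


def write_gmt(db: PathwayDB, path: str | Path) -> Path:
    """Write a PathwayDB as GMT with members in stable sorted order."""
    path = Path(path)
    with open(path, "w") as fh:
        for p in db:
            for m in p.members:
                if "\t" in m:
                    raise ValueError(f"member {m!r} of {p.pathway_id} contains a tab")
            fields = [p.pathway_id, p.source, *sorted(p.members)]
            fh.write("\t".join(fields) + "\n")
    return path


@dataclass(frozen=True)
class MappingReport:
    n_input: int
    n_mapped: int
    n_unmapped: int
    n_ambiguous: int
    unmapped_ids: frozenset


class GeneMapping:
    """Source id → set-of-target-symbols lookup (e.g. rat → human)."""

    def __init__(self, table: dict) -> None:
        self._map = {str(k): frozenset(str(t).upper() for t in v) for k, v in table.items()}

    def __len__(self) -> int:
        return len(self._map)

    def targets(self, source_id: str) -> frozenset:
        return self._map.get(str(source_id), frozenset())

    def is_ambiguous(self, source_id: str) -> bool:
        return len(self.targets(source_id)) > 1

    def is_unmapped(self, source_id: str) -> bool:
        return len(self.targets(source_id)) == 0


def read_mapping(path: str | Path) -> GeneMapping:
    """Read a two-column (source TAB target) mapping file, no header."""
    table = pd.read_csv(path, sep="\t", header=None, names=["source", "target"], dtype=str)
    out: dict[str, set] = {}
    for s, t in zip(table["source"], table["target"]):
        out.setdefault(s, set()).add(t)
    return GeneMapping(out)


def map_genes(
    ids, mapping: GeneMapping | None, policy: str = "expand"
) -> tuple[frozenset, MappingReport]:
    """Map a set of source ids into the pathway namespace.

    ``expand`` takes the union of all targets of all ids; ``drop_ambiguous``
    lets only one-to-one ids contribute.  ``mapping=None`` means the ids are
    already in the pathway namespace (identity up to uppercasing).
    Unmapped ids are reported, never fatal.
    """
    if policy not in ("expand", "drop_ambiguous"):
        raise ValueError(f"unknown mapping policy {policy!r}")
    ids = [str(i) for i in ids]
    if mapping is None:
        out = frozenset(i.upper() for i in ids)
        return out, MappingReport(len(ids), len(ids), 0, 0, frozenset())
    out_set: set = set()
    unmapped, ambiguous, mapped = [], 0, 0
    for i in ids:
        t = mapping.targets(i)
        if not t:
            unmapped.append(i)
            continue
        mapped += 1
        if len(t) > 1:
            ambiguous += 1
            if policy == "drop_ambiguous":
                continue
        out_set |= t
    return frozenset(out_set), MappingReport(
        len(ids), mapped, len(unmapped), ambiguous, frozenset(unmapped)
    )
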