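"""Gene set collections: GMT I/O and projection onto an expression gene universe.

A collection is an ordered mapping of set name -> member gene identifiers.
Before scoring, a collection is projected onto the gene axis of an expression
matrix, yielding per-set integer column indices (a sparse view of the dense
set-by-gene membership matrix, which is never materialized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneSetCollection",
    "SetIndex",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "build_set_index",
]


class GmtParseError(ValueError):
    """Raised for malformed GMT content; carries the offending line number."""


@dataclass
class GeneSetCollection:
    """Named, unordered gene sets with optional free-text descriptions.

    Invariants enforced at construction: set names unique (guaranteed by the
    dict), every set nonempty, and member identifiers unique within a set.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} contains duplicate gene identifiers")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.descriptions == other.descriptions


@dataclass
class SetIndex:
    """Per-set column indices into a fixed gene axis.

    ``indices[name]`` holds the unique, sorted column positions of the set's
    members that are present in the gene universe; ``dropped`` lists sets
    removed for falling below the minimum size after intersection.
    """

    indices: dict[str, np.ndarray]
    dropped: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return list(self.indices)

    @property
    def sizes(self) -> dict[str, int]:
        return {name: idx.size for name, idx in self.indices.items()}

    def __len__(self) -> int:
        return len(self.indices)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, members...).

    Duplicate member identifiers within one line are removed, keeping first
    occurrence. Lines with fewer than three fields and duplicate set names
    raise :class:`GmtParseError` naming the line.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description, *members = fields
            if name in sets:
                raise GmtParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen: dict[str, None] = {}
            for gene in members:
                if gene and gene not in seen:
                    seen[gene] = None
            if not seen:
                raise GmtParseError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = list(seen)
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection to GMT, preserving set order. UTF-8, no quoting."""
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in collection:
            description = collection.descriptions.get(name, "")
            handle.write("\t".join([name, description, *members]) + "\n")


def build_set_index(
    collection: GeneSetCollection,
    gene_ids: list[str],
    min_set_size: int = 5,
) -> SetIndex:
    """Map a collection onto a gene universe as per-set column indices.

    Members absent from ``gene_ids`` are dropped; sets left with fewer than
    ``min_set_size`` members are dropped and recorded. Matching is exact
    string equality on identifiers.

    Raises
    ------
    ValueError
        If ``gene_ids`` contains duplicates, or if every set is dropped
        (almost always an identifier-namespace mismatch).
    """
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene_ids must be unique")
    position = {gene: i for i, gene in enumerate(gene_ids)}
    indices: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for name, members in collection:
        cols = sorted(position[g] for g in members if g in position)
        if len(cols) < min_set_size:
            dropped.append(name)
        else:
            indices[name] = np.asarray(cols, dtype=np.intp)
    if not indices:
        raise ValueError(
            "all gene sets were dropped after intersection with the expression genes; "
            "check that the gene identifier namespaces match "
            "(e.g. symbols vs Ensembl IDs)"
        )
    return SetIndex(indices=indices, dropped=dropped)
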