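"""Gene-set (pathway) collections: GMT I/O, category annotation, size filtering.

A pathway here is a named set of gene symbols with a category label
(e.g. "Signal transduction").  Collections keep a stable, deterministic
pathway order so that binary profiles built over the same collection are
directly comparable position by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Pathway",
    "PathwayCollection",
    "read_gmt",
    "write_gmt",
    "read_category_table",
    "write_category_table",
    "filter_pathways",
]


@dataclass(frozen=True)
class Pathway:
    """A named gene set.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    name : str
        Human-readable label (the GMT description field).
    genes : frozenset of str
        Member gene symbols, uppercase.
    category : str
        Pathway category, e.g. ``"Signal transduction"``; ``"Unknown"``
        when no annotation is available.
    """

    id: str
    name: str
    genes: frozenset = field(default_factory=frozenset)
    category: str = "Unknown"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.id!r} has no genes")
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def size(self) -> int:
        return len(self.genes)


class PathwayCollection:
    """An ordered collection of :class:`Pathway` with a gene universe.

    Order is lexicographic by pathway id unless ``sort=False`` is given,
    in which case input order is preserved.  The universe is the union of
    all member gene sets.
    """

    def __init__(self, pathways: Iterable[Pathway], sort: bool = True) -> None:
        pathways = list(pathways)
        ids = [p.id for p in pathways]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate pathway id {dup!r} in collection")
        if sort:
            pathways = sorted(pathways, key=lambda p: p.id)
        self._pathways = pathways
        self._by_id = {p.id: p for p in pathways}

    @property
    def pathways(self) -> list:
        return list(self._pathways)

    @property
    def ids(self) -> list:
        return [p.id for p in self._pathways]

    @property
    def universe(self) -> frozenset:
        out: set = set()
        for p in self._pathways:
            out |= p.genes
        return frozenset(out)

    @property
    def category_index(self) -> dict:
        idx: dict = {}
        for p in self._pathways:
            idx.setdefault(p.category, []).append(p.id)
        return idx

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self._pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._by_id[pathway_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCollection):
            return NotImplemented
        return self._pathways == other._pathways

    def with_categories(self, categories: Mapping[str, str]) -> "PathwayCollection":
        """Return a new collection with categories attached from a mapping.

        Ids absent from the mapping keep / get category ``"Unknown"``.
        """
        return PathwayCollection(
            [replace(p, category=categories.get(p.id, "Unknown")) for p in self._pathways],
            sort=False,
        )


def read_gmt(path, sort: bool = True) -> PathwayCollection:
    """Read a GMT file (set name TAB description TAB gene ...).

    Gene symbols are uppercased and deduplicated within each line.
    Raises ``ValueError`` naming the line number for malformed lines and
    for duplicate pathway ids.
    """
    pathways = []
    seen: set = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            pid, name, *genes = fields
            if pid in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate pathway id {pid!r}")
            seen.add(pid)
            gene_set = frozenset(g.strip().upper() for g in genes if g.strip())
            if not gene_set:
                raise ValueError(f"{path}: line {lineno}: pathway {pid!r} has no genes")
            pathways.append(Pathway(id=pid, name=name, genes=gene_set))
    return PathwayCollection(pathways, sort=sort)


def write_gmt(collection: PathwayCollection, path) -> None:
    """Write a collection as GMT; genes sorted for a stable byte layout."""
    with open(path, "wt", encoding="utf-8") as fh:
        for p in collection:
            fh.write("\t".join([p.id, p.name, *sorted(p.genes)]) + "\n")


def read_category_table(path, header: bool = False) -> dict:
    """Read a two-column TSV mapping pathway id to category.

    Conflicting categories for one id raise ``ValueError``.  An empty
    file yields an empty mapping (downstream every id defaults to
    ``"Unknown"``).
    """
    mapping: dict = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            pid, category = fields[0].strip(), fields[1].strip()
            if pid in mapping and mapping[pid] != category:
                raise ValueError(
                    f"{path}: line {lineno}: conflicting categories for {pid!r}: "
                    f"{mapping[pid]!r} vs {category!r}"
                )
            mapping[pid] = category
    return mapping


def write_category_table(categories: Mapping[str, str], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for pid in sorted(categories):
            fh.write(f"{pid}\t{categories[pid]}\n")


def filter_pathways(
    collection: PathwayCollection,
    min_size: int = 16,
    max_size: int = 350,
    excluded_categories: Iterable[str] = (),
    measured_genes: Iterable[str] | None = None,
) -> PathwayCollection:
    """Filter a collection by gene-set size and category.

    Retains pathways with ``min_size <= size <= max_size`` whose category
    is not excluded; with the defaults this drops sets smaller than 16 or
    larger than 350 genes.  Size is measured on the full gene set unless
    ``measured_genes`` is given, in which case only genes in that set
    count (sizing against the genes actually present on a platform).
    Order is preserved; the universe is recomputed.  Idempotent.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    excluded = set(excluded_categories)
    measured = None if measured_genes is None else frozenset(g.upper() for g in measured_genes)
    kept = []
    for p in collection:
        if p.category in excluded:
            continue
        size = p.size if measured is None else len(p.genes & measured)
        if min_size <= size <= max_size:
            kept.append(p)
    return PathwayCollection(kept, sort=False)
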