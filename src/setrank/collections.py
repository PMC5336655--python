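"""Gene-set collections: loading, validation, filtering, indexing.

A collection bundles gene sets from one or more annotation databases
(GO, KEGG, Reactome dumps, ...) so that they can be queried as a single
resource.  Gene identifiers are opaque, case-sensitive strings; no ID
mapping is performed here — that belongs to upstream annotation tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping


class GMTParseError(ValueError):
    """Raised for malformed GMT / table input."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with database provenance.

    Parameters
    ----------
    set_id : str
        Opaque identifier, unique within a collection.
    name : str
        Human-readable label.
    db : str
        Tag naming the database of origin (e.g. ``"GOBP"``, ``"KEGG"``).
    genes : frozenset of str
        Member gene identifiers; must be non-empty.
    """

    set_id: str
    name: str
    db: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} has no genes")
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An indexed list of gene sets.

    The ``index`` maps each gene to the IDs of the sets containing it and
    is always exactly the inverse of set membership.
    """

    sets: list
    max_set_size: int | None = None
    index: dict = field(init=False)

    def __post_init__(self):
        self.index = build_index(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def get(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def by_id(self) -> Mapping[str, GeneSet]:
        return {s.set_id: s for s in self.sets}

    def all_genes(self) -> frozenset:
        return frozenset(self.index)

    def sets_containing(self, gene: str) -> list:
        return list(self.index.get(gene, ()))


def build_index(sets: Iterable[GeneSet]) -> dict:
    """Invert set membership: gene ID -> list of set IDs containing it.

    Raises ``ValueError`` on duplicate set IDs.
    """
    index: dict = {}
    seen = set()
    for s in sets:
        if s.set_id in seen:
            raise ValueError(f"duplicate set_id {s.set_id!r}")
        seen.add(s.set_id)
        for g in s.genes:
            index.setdefault(g, []).append(s.set_id)
    return index


def read_gmt(path, db: str | None = None) -> GeneSetCollection:
    """Read a GMT file (one set per line: id, description, genes...).

    The first field is used as the set ID, the second as the name.  The
    database tag is ``db`` if given, otherwise the description field.
    Duplicate genes within a line are collapsed.
    """
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, desc, genes = fields[0], fields[1], fields[2:]
            genes = frozenset(g for g in genes if g)
            if not genes:
                raise GMTParseError(f"{path}:{lineno}: set {set_id!r} has no genes")
            sets.append(GeneSet(set_id, desc or set_id, db if db is not None else desc, genes))
    if not sets:
        raise GMTParseError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def read_set_table(path, sep: str = "\t") -> GeneSetCollection:
    """Read a 3-column table (set_id, db, gene), one membership per row.

    Suited to database dump tables.  The set name defaults to the set ID.
    """
    members: dict = {}
    dbs: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split(sep)
            if len(fields) != 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            set_id, db, gene = fields
            members.setdefault(set_id, set()).add(gene)
            dbs[set_id] = db
    if not members:
        raise GMTParseError(f"{path}: empty table")
    sets = [GeneSet(sid, sid, dbs[sid], frozenset(gs)) for sid, gs in members.items()]
    return GeneSetCollection(sets)


def merge_collections(*collections: GeneSetCollection) -> GeneSetCollection:
    """Union of several collections (set IDs must not collide)."""
    sets = [s for c in collections for s in c.sets]
    return GeneSetCollection(sets)


def filter_collection(
    collection: GeneSetCollection,
    min_size: int = 3,
    max_size: int = 500,
    background: frozenset | set | None = None,
) -> GeneSetCollection:
    """Restrict sets to a background universe and a size window.

    Each set is first intersected with ``background`` (default: all genes
    in the collection), then retained iff ``min_size <= |intersection| <=
    max_size``.  Intersecting *before* size filtering keeps every set's
    effective size equal to the size used by all downstream tests, which
    are relative to the background universe L.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    if background is not None and not background:
        raise ValueError("background set is empty")
    bg = frozenset(background) if background is not None else None
    out = []
    for s in collection.sets:
        genes = s.genes if bg is None else s.genes & bg
        if min_size <= len(genes) <= max_size:
            out.append(GeneSet(s.set_id, s.name, s.db, genes))
    return GeneSetCollection(out, max_set_size=max_size)
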