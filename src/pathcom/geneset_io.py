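"""Reading and writing gene-set collections and their companion files.

Gene sets travel in GMT (the tab-separated MSigDB distribution format:
name, description, then one gene symbol per field). Category maps are
two-column TSV files assigning pathways to curated category labels, and
query gene lists are plain one-symbol-per-line text.

Gene symbols are case-folded to upper case on input so that collections
and query lists with mixed capitalisation compare correctly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: id prefixes that identify the originating database of an MSigDB-style set
KNOWN_SOURCE_PREFIXES = ("KEGG", "REACTOME", "GOBP", "GOMF")


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols.

    Parameters
    ----------
    id
        Unique identifier within a collection.
    name
        Display name; equals ``id`` for GMT input.
    source
        Free-form database tag (e.g. ``"KEGG"``), ``"unknown"`` if the id
        carries no recognised prefix.
    genes
        Upper-cased gene symbols; non-empty.
    """

    id: str
    name: str
    source: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.id!r} has no genes")
        if any(not g for g in self.genes):
            raise ValueError(f"gene set {self.id!r} contains an empty gene symbol")

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """An ordered collection of :class:`GeneSet` with a gene universe.

    The universe defaults to the union of all member sets — the only
    background computable from the inputs alone — and may be overridden
    with any superset (e.g. all annotated human genes).
    """

    def __init__(self, sets: Iterable[GeneSet], universe: set[str] | None = None):
        self.sets: list[GeneSet] = list(sets)
        seen: set[str] = set()
        for s in self.sets:
            if s.id in seen:
                raise ValueError(f"duplicate pathway id {s.id!r}")
            seen.add(s.id)
        self._by_id = {s.id: s for s in self.sets}
        union: set[str] = set()
        for s in self.sets:
            union |= s.genes
        if universe is None:
            self.universe: frozenset[str] = frozenset(union)
        else:
            universe = {g.upper() for g in universe}
            missing = union - universe
            if missing:
                raise ValueError(
                    f"universe is missing {len(missing)} gene(s) present in the "
                    f"collection (e.g. {sorted(missing)[:3]})"
                )
            self.universe = frozenset(universe)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, pathway_id: str) -> GeneSet:
        return self._by_id[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sets]

    @property
    def universe_size(self) -> int:
        return len(self.universe)


@dataclass
class CategoryMap:
    """Mapping pathway id -> curated category label; pathways may be absent."""

    assignments: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.assignments)

    def __getitem__(self, pathway_id: str) -> str:
        return self.assignments[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.assignments


def infer_source(pathway_id: str) -> str:
    """Infer the database tag from a pathway id prefix, else ``"unknown"``."""
    head = pathway_id.split("_", 1)[0].upper()
    return head if head in KNOWN_SOURCE_PREFIXES else "unknown"


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Each non-empty line must have at least three tab-separated fields:
    name, description, then gene symbols. Duplicate genes within a line
    are deduplicated; symbols are upper-cased.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name = fields[0]
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(id=name, name=name, source=infer_source(name), genes=genes))
    return GeneSetCollection(sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; genes sorted for reproducible output."""
    path = Path(path)
    with path.open("w") as fh:
        for s in collection:
            fh.write("\t".join([s.id, s.name, *sorted(s.genes)]) + "\n")


def read_category_map(path: str | Path) -> CategoryMap:
    """Read a two-column TSV (pathway id, category label).

    Duplicate pathway ids resolve last-wins, with a logged warning.
    """
    path = Path(path)
    assignments: dict[str, str] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns "
                    "(pathway id, category)"
                )
            pid, label = fields[0], fields[1]
            if pid in assignments:
                logger.warning(
                    "%s:%d: duplicate pathway id %r; keeping last label %r",
                    path, lineno, pid, label,
                )
            assignments[pid] = label
    return CategoryMap(assignments)


def write_category_map(categories: CategoryMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for pid, label in categories.assignments.items():
            fh.write(f"{pid}\t{label}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list; upper-cased and deduplicated."""
    path = Path(path)
    genes: set[str] = set()
    with path.open() as fh:
        for raw in fh:
            sym = raw.strip()
            if sym:
                genes.add(sym.upper())
    if not genes:
        raise ParseError(f"{path}: no genes read")
    return genes


def read_universe(path: str | Path) -> set[str]:
    """Read an explicit background-universe gene list (same format)."""
    return read_gene_list(path)
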