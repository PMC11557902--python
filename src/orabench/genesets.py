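"""Gene-set libraries and gene lists.

A gene-set library is an ordered collection of named gene sets (the GMT
format used by MSigDB and most enrichment tools).  This module reads and
writes that format, restricts libraries to a background of detected genes,
filters sets by size, and implements the "append the background as a gene
set" workaround that forces tools with the background problem to keep
unannotated genes in the universe.

Gene identifiers are matched as exact, case-sensitive strings.  No symbol
normalisation or cross-namespace mapping is attempted: enrichment tools
operate on the identifiers verbatim, and silently "fixing" symbols is a
classic source of irreproducibility.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

logger = logging.getLogger(__name__)

#: Reserved identifier for the appended whole-background set.
UNIVERSE_SET_ID = "__UNIVERSE__"


class GmtParseError(ValueError):
    """Raised when a GMT file cannot be parsed."""


@dataclass(frozen=True)
class GeneSet:
    """One named gene set: identifier, free-text description, members.

    Members are an ordered tuple with no duplicates and at least one entry.
    """

    set_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValueError("gene set requires a non-empty set_id")
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.set_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.set_id!r} has duplicate members")

    @cached_property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free list of gene identifiers with a role.

    ``role`` is ``"foreground"`` (the selected genes of interest) or
    ``"background"`` (all genes reliably detected in the assay — the
    universe of the hypergeometric test).
    """

    role: str
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.role not in ("foreground", "background"):
            raise ValueError(f"unknown gene list role {self.role!r}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("gene list contains duplicate identifiers")

    @classmethod
    def from_ids(cls, role: str, ids: Iterable[str]) -> "GeneList":
        """Build a list from possibly-duplicated ids, keeping first-seen order."""
        seen: dict[str, None] = {}
        n_dup = 0
        for g in ids:
            if g in seen:
                n_dup += 1
            else:
                seen[g] = None
        if n_dup:
            logger.warning("dropped %d duplicate ids while building %s list", n_dup, role)
        return cls(role, tuple(seen))

    @cached_property
    def id_set(self) -> frozenset[str]:
        return frozenset(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __contains__(self, gene: object) -> bool:
        return gene in self.id_set


class GeneSetLibrary:
    """An ordered mapping ``set_id -> GeneSet`` with unique identifiers."""

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.set_id in self._sets:
            raise ValueError(f"duplicate set_id {gene_set.set_id!r}")
        self._sets[gene_set.set_id] = gene_set

    @property
    def set_ids(self) -> tuple[str, ...]:
        return tuple(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, set_id: object) -> bool:
        return set_id in self._sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetLibrary):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneSetLibrary({len(self)} sets)"


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Parse a GMT file (tab-separated: id, description, member genes...).

    Duplicate member ids within a line are collapsed with a warning; empty
    member fields are ignored; lines whose member list ends up empty are
    dropped with a warning; a duplicate set id raises; a line with fewer
    than three fields raises :class:`GmtParseError` naming the line number.
    """
    lib = GeneSetLibrary()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if line == "":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            set_id, description = fields[0], fields[1]
            members: dict[str, None] = {}
            n_dup = 0
            for g in fields[2:]:
                if g == "":
                    continue
                if g in members:
                    n_dup += 1
                else:
                    members[g] = None
            if n_dup:
                logger.warning(
                    "%s: line %d: collapsed %d duplicate member ids in set %s",
                    path, lineno, n_dup, set_id,
                )
            if not members:
                logger.warning("%s: line %d: dropping set %s with no members", path, lineno, set_id)
                continue
            if set_id in lib:
                raise ValueError(f"{path}: line {lineno}: duplicate set_id {set_id!r}")
            lib.add(GeneSet(set_id, description, tuple(members)))
    return lib


def write_gmt(lib: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in lib:
            fh.write("\t".join((gs.set_id, gs.description, *gs.members)) + "\n")


def read_gene_list(path: str | Path, role: str) -> GeneList:
    """Read a one-id-per-line text file; ``#`` comment lines are skipped."""
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line)
    return GeneList.from_ids(role, ids)


def write_gene_list(genes: GeneList | Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(g + "\n")


def restrict_to_background(lib: GeneSetLibrary, bg: GeneList | Iterable[str]) -> GeneSetLibrary:
    """Intersect every set's members with the background.

    Sets emptied by the intersection are removed.  The input library is not
    modified.  Idempotent.
    """
    bg_set = bg.id_set if isinstance(bg, GeneList) else frozenset(bg)
    if not bg_set:
        raise ValueError("background is empty")
    out = GeneSetLibrary()
    n_removed = 0
    for gs in lib:
        members = tuple(g for g in gs.members if g in bg_set)
        if not members:
            n_removed += 1
            continue
        out.add(GeneSet(gs.set_id, gs.description, members))
    if n_removed:
        logger.info("restrict_to_background removed %d sets with no background members", n_removed)
    return out


def filter_by_size(
    lib: GeneSetLibrary, min_size: int, max_size: int | None = None
) -> GeneSetLibrary:
    """Keep sets with ``min_size <= |members| <= max_size`` (no upper bound if None)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size is not None and min_size > max_size:
        raise ValueError(f"min_size ({min_size}) exceeds max_size ({max_size})")
    out = GeneSetLibrary()
    for gs in lib:
        if len(gs) < min_size:
            continue
        if max_size is not None and len(gs) > max_size:
            continue
        out.add(gs)
    return out


def annotated_genes(lib: GeneSetLibrary) -> frozenset[str]:
    """Union of all member genes across all sets (the "annotated" genes)."""
    out: set[str] = set()
    for gs in lib:
        out.update(gs.members)
    return frozenset(out)


def append_universe_set(
    lib: GeneSetLibrary, bg: GeneList | Iterable[str], set_id: str = UNIVERSE_SET_ID
) -> GeneSetLibrary:
    """Return the library plus one set holding the entire background.

    This is the published workaround for the background problem: a tool
    that silently drops unannotated genes from the universe is forced to
    keep them, because every background gene is now annotated.  Downstream
    analysis must never report (or count as a test) the reserved set; the
    engine in :mod:`orabench.ora` excludes it.
    """
    if set_id in lib:
        raise ValueError(f"reserved universe set id {set_id!r} already present in library")
    ids = tuple(bg.ids) if isinstance(bg, GeneList) else tuple(dict.fromkeys(bg))
    out = GeneSetLibrary(lib)
    out.add(GeneSet(set_id, "whole background appended to defeat universe shrinkage", ids))
    return out
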