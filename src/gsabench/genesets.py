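"""Gene-set knowledge base: GMT/GMX parsing, universe restriction, overlap.

Gene sets are named groups of gene identifiers drawn from a curated knowledge
base (MSigDB-style collections).  The two interchange formats supported are
the MSigDB dialects:

* GMT — one set per *row*: ``name<TAB>description<TAB>gene1<TAB>gene2...``
* GMX — one set per *column*: row 1 holds names, row 2 descriptions, and the
  remaining rows list genes downward.

Identifiers are matched by exact string comparison after whitespace trimming;
case is preserved (MSigDB symbols are conventionally uppercase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence


class GeneSetParseError(ValueError):
    """Raised for malformed GMT/GMX records."""


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers.

    Parameters
    ----------
    name : str
        Unique, non-empty identifier of the set.
    description : str
        Free-text annotation (``"na"`` is the conventional placeholder).
    genes : tuple of str
        Unique gene identifiers, order of first appearance preserved.
    """

    name: str
    description: str = "na"
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def restrict_to_universe(self, universe: Iterable[str]) -> "GeneSet":
        """Intersect the set with a dataset's gene universe.

        The name and description are preserved; gene order follows the set.
        An empty intersection is returned (with a warning) rather than raised,
        so callers can decide to drop the set via :func:`filter_by_size`.
        """
        uni = set(universe)
        if not uni:
            raise ValueError("universe must be non-empty")
        kept = tuple(g for g in self.genes if g in uni)
        if not kept:
            warnings.warn(
                f"gene set {self.name!r} has no genes in the universe",
                stacklevel=2,
            )
        return GeneSet(self.name, self.description, kept)


def overlap_proportion(
    secondary: GeneSet, target: GeneSet, denominator: str = "secondary"
) -> float:
    """Fraction of ``secondary`` contained in ``target``.

    With ``denominator="secondary"`` (default) a small set fully inside the
    target scores 1.0 — the scale on which off-target sensitivity of a method
    grows with the share of the secondary set carrying injected signal.  The
    alternative ``denominator="target"`` normalises by the target size.
    """
    if len(secondary) == 0:
        raise ValueError("secondary set is empty")
    inter = len(set(secondary.genes) & set(target.genes))
    if denominator == "secondary":
        return inter / len(secondary)
    if denominator == "target":
        if len(target) == 0:
            raise ValueError("target set is empty")
        return inter / len(target)
    raise ValueError(f"unknown denominator {denominator!r}")


class GeneSetCollection:
    """Ordered collection of uniquely named :class:`GeneSet` objects."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: list[GeneSet] = list(sets)
        self._index: dict[str, GeneSet] = {}
        for s in self.sets:
            if s.name in self._index:
                raise ValueError(f"duplicate gene set name {s.name!r}")
            self._index[s.name] = s

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def restrict_to_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        uni = set(universe)
        return GeneSetCollection(s.restrict_to_universe(uni) for s in self.sets)

    def filter_by_size(
        self, min_size: int = 1, max_size: int | None = None
    ) -> "GeneSetCollection":
        """Retain sets whose size lies in ``[min_size, max_size]``.

        ``max_size=None`` means unbounded.  Method defaults differ (SAFE uses
        a minimum of 2, sigPathway 1 with a maximum of 10,000); callers pass
        the appropriate bounds.
        """
        if min_size < 1:
            raise ValueError("min_size must be >= 1")
        if max_size is not None and min_size > max_size:
            raise ValueError("min_size exceeds max_size")
        hi = float("inf") if max_size is None else max_size
        kept = [s for s in self.sets if min_size <= len(s) <= hi]
        if not kept:
            warnings.warn("no gene sets survive the size filter", stacklevel=2)
        return GeneSetCollection(kept)


def _parse_gmt_lines(lines: Iterable[str]) -> list[GeneSet]:
    sets = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2:
            raise GeneSetParseError(
                f"line {lineno}: expected at least 2 tab-separated fields"
            )
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            warnings.warn(
                f"line {lineno}: duplicate genes in set {name!r} removed",
                stacklevel=3,
            )
        if not deduped:
            raise GeneSetParseError(f"line {lineno}: set {name!r} has no genes")
        sets.append(GeneSet(name, desc or "na", tuple(deduped)))
    return sets


def _parse_gmx_lines(lines: Sequence[str], sep: str) -> list[GeneSet]:
    rows = [line.rstrip("\n").split(sep) for line in lines if line.strip()]
    if len(rows) < 2:
        raise GeneSetParseError("GMX file needs a name row and a description row")
    names = [c.strip() for c in rows[0]]
    descs = [c.strip() for c in rows[1]]
    ncol = len(names)
    sets = []
    for j, name in enumerate(names):
        if not name:
            continue
        desc = descs[j] if j < len(descs) else "na"
        genes = []
        for row in rows[2:]:
            if j < len(row):
                tok = row[j].strip()
                if tok:
                    genes.append(tok)
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            warnings.warn(
                f"column {j + 1}: duplicate genes in set {name!r} removed",
                stacklevel=3,
            )
        if not deduped:
            raise GeneSetParseError(f"column {j + 1}: set {name!r} has no genes")
        sets.append(GeneSet(name, desc or "na", tuple(deduped)))
    if ncol and not sets:
        raise GeneSetParseError("GMX file contains no named sets")
    return sets


def read_gene_sets(path: str | Path, dialect: str | None = None) -> GeneSetCollection:
    """Read a GMT or GMX gene-set file.

    Parameters
    ----------
    path : path-like
    dialect : {"gmt", "gmx"}, optional
        Inferred from the file extension when omitted.  GMX accepts either
        tab- or comma-separated columns (tab is canonical).
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if dialect not in ("gmt", "gmx"):
        raise ValueError(f"unknown gene-set dialect {dialect!r}")
    text = path.read_text()
    lines = text.splitlines()
    if dialect == "gmt":
        sets = _parse_gmt_lines(lines)
    else:
        sep = "\t" if any("\t" in ln for ln in lines[:2]) else ","
        sets = _parse_gmx_lines(lines, sep)
    return GeneSetCollection(sets)


def write_gene_sets(
    coll: GeneSetCollection, path: str | Path, dialect: str = "gmt"
) -> None:
    """Write a collection in GMT (row-wise) or GMX (column-wise) form."""
    path = Path(path)
    if dialect == "gmt":
        with path.open("w") as fh:
            for s in coll:
                fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
    elif dialect == "gmx":
        depth = max((len(s) for s in coll), default=0)
        rows = [[s.name for s in coll], [s.description for s in coll]]
        for i in range(depth):
            rows.append([s.genes[i] if i < len(s) else "" for s in coll])
        with path.open("w") as fh:
            for row in rows:
                fh.write("\t".join(row) + "\n")
    else:
        raise ValueError(f"unknown gene-set dialect {dialect!r}")
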