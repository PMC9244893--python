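"""Genomic interval primitives: 0-based half-open coordinates, BED I/O,
overlap/merge/nearest/coverage set operations.

Every other module computes on these types.  All coordinates inside the
package are 0-based half-open (BED native); 1-based inputs (VCF, display
tables) are converted at the parser boundary.  Chromosome names are taken
verbatim — no ``chr`` prefix normalisation is applied unless a caller
strips/adds it explicitly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Raised for malformed BED-family lines; message names the line number."""


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).  Sorting is by
    (chrom lexicographic, start, end).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol: {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __lt__(self, other: "GenomicInterval") -> bool:
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class GenomeTable(dict):
    """Mapping chrom -> length in bp, with positive-length validation."""

    def __setitem__(self, chrom: str, length: int) -> None:
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        super().__setitem__(chrom, int(length))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeTable":
        table = cls()
        for chrom, length in pairs:
            table[chrom] = length
        return table

    @property
    def total_bp(self) -> int:
        return sum(self.values())


def read_genome_table(source) -> GenomeTable:
    """Read a two-column ``chrom.sizes`` file (chrom<TAB>length)."""
    table = GenomeTable()
    with _as_text_stream(source) as stream:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"line {lineno}: expected 2 columns, got {len(fields)}")
            try:
                table[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return table


def _as_text_stream(source):
    if hasattr(source, "read"):
        return _NonClosing(source)
    return open(source, "rt")


class _NonClosing:
    def __init__(self, stream):
        self._stream = stream

    def __enter__(self):
        return self._stream

    def __exit__(self, *exc):
        return False

    def __iter__(self):
        return iter(self._stream)


_HEADER_PREFIXES = ("track", "browser", "#")


def read_bed(source, min_columns: int = 3) -> list[GenomicInterval]:
    """Parse a BED3/BED6 stream or path into intervals, in file order.

    Strand is read from column 6 when present; name from column 4; score
    from column 5 when numeric.  Malformed lines raise :class:`BedParseError`
    naming the offending line.
    """
    out: list[GenomicInterval] = []
    with _as_text_stream(source) as stream:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(_HEADER_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < min_columns or len(fields) < 3:
                raise BedParseError(
                    f"line {lineno}: expected >= {max(min_columns, 3)} columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"line {lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(
                    GenomicInterval(fields[0], start, end, strand=strand, name=name, score=score)
                )
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], destination) -> None:
    """Write intervals as BED6 (BED3 fields always; name/score/strand dotted
    when absent)."""
    own = not hasattr(destination, "write")
    stream = open(destination, "wt") if own else destination
    try:
        for iv in intervals:
            score = "." if iv.score is None else format(iv.score, "g")
            name = iv.name if iv.name is not None else "."
            stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
    finally:
        if own:
            stream.close()


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test; abutting intervals do not overlap; strand ignored."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of covered bases: sorted, non-overlapping, non-abutting output.

    Abutting inputs (``[10,20)`` + ``[20,30)``) are joined into one interval.
    Name/score/strand are dropped (the merged coordinate has no single source).
    """
    ordered = sorted(intervals, key=GenomicInterval.sort_key)
    out: list[GenomicInterval] = []
    for iv in ordered:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


class NoNeighbourError(LookupError):
    """Raised when a nearest-neighbour query has no same-chromosome target."""


def gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Bases strictly between two same-chromosome intervals (0 when they
    overlap or abut)."""
    if a.chrom != b.chrom:
        raise ValueError("gap undefined across chromosomes")
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start - b.end, b.start - a.end, 0)


def nearest(
    query: GenomicInterval, targets: Sequence[GenomicInterval]
) -> tuple[GenomicInterval, int]:
    """Closest target by gap distance (0 when overlapping).

    Ties are broken by smaller target start, then by name, so reports are
    reproducible.  Raises :class:`NoNeighbourError` when no target shares
    the query's chromosome.
    """
    same = [t for t in targets if t.chrom == query.chrom]
    if not same:
        raise NoNeighbourError(f"no target on chromosome {query.chrom!r}")
    return min(
        ((t, gap(query, t)) for t in same),
        key=lambda pair: (pair[1], pair[0].start, pair[0].name or ""),
    )


def covered_bases(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.width for iv in merge(intervals))


def coverage_fraction(intervals: Iterable[GenomicInterval], genome: GenomeTable) -> float:
    """Fraction of the genome covered by the union of ``intervals``."""
    merged = merge(intervals)
    for iv in merged:
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} not in genome table")
        if iv.end > genome[iv.chrom]:
            raise ValueError(f"interval {iv} extends past chromosome end {genome[iv.chrom]}")
    total = genome.total_bp
    if total == 0:
        return 0.0
    return sum(iv.width for iv in merged) / total


class IntervalIndex:
    """Per-chromosome interval tree for fast overlap queries.

    Wraps :mod:`intervaltree`; built once from a collection, then queried
    with half-open semantics matching :func:`overlaps`.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [hit.data for hit in tree.overlap(query.start, query.end)]
        hits.sort(key=GenomicInterval.sort_key)
        return hits

    def any_overlap(self, query: GenomicInterval) -> bool:
        tree = self._trees.get(query.chrom)
        return tree is not None and bool(tree.overlap(query.start, query.end))
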