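"""Fixed-resolution Hi-C interaction tables and the post-caller filters.

Interaction callers that fit a background model (MaxHiC, Fit-Hi-C, ...)
emit one row per bin pair with a read count and a raw P-value.  This module
consumes such tables (BEDPE-like, 8 columns by default), applies
Benjamini-Hochberg adjustment across the whole intra-chromosomal table, and
keeps interactions that are significant (adjusted P < 0.05), supported by
at least 5 read pairs, and span more than 5 kb between bin starts.  It then
answers anchor-overlap and partner queries for variant-to-gene linking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from snplink.intervals import GenomicInterval, IntervalIndex, _as_text_stream, BedParseError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_COUNT = 5
DEFAULT_MIN_BIN_DISTANCE = 5000
DEFAULT_RESOLUTION = 5000


@dataclass(frozen=True, order=True)
class GenomicBin:
    """Bin ``index`` of width ``resolution`` on ``chrom``:
    interval ``[index*resolution, (index+1)*resolution)``."""

    chrom: str
    index: int
    resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"negative bin index {self.index}")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def start(self) -> int:
        return self.index * self.resolution

    @property
    def end(self) -> int:
        return (self.index + 1) * self.resolution

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def pos_to_bin(chrom: str, pos: int, resolution: int = DEFAULT_RESOLUTION) -> GenomicBin:
    """Map a 0-based position to its containing bin (floor division)."""
    if pos < 0:
        raise ValueError(f"negative position {pos}")
    return GenomicBin(chrom, pos // resolution, resolution)


@dataclass(frozen=True)
class InteractionRecord:
    """One bin pair with read support and significance.

    Stored in canonical orientation (``bin_a <= bin_b``); ``adj_p`` is
    computed by :func:`bh_adjust` / :func:`filter_interactions`, never read
    from input.
    """

    bin_a: GenomicBin
    bin_b: GenomicBin
    read_count: int
    p_value: float
    adj_p: float | None = None

    def __post_init__(self) -> None:
        if self.bin_a.resolution != self.bin_b.resolution:
            raise ValueError("anchor bins must share a resolution")
        if self.read_count < 0:
            raise ValueError("read count must be non-negative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.bin_b < self.bin_a:
            a, b = self.bin_a, self.bin_b
            object.__setattr__(self, "bin_a", b)
            object.__setattr__(self, "bin_b", a)

    @property
    def intra_chromosomal(self) -> bool:
        return self.bin_a.chrom == self.bin_b.chrom

    @property
    def bin_distance(self) -> int:
        """|start_a - start_b| in bp; only meaningful intra-chromosomally."""
        return abs(self.bin_a.start - self.bin_b.start)


def canonical(bin_a: GenomicBin, bin_b: GenomicBin) -> tuple[GenomicBin, GenomicBin]:
    return (bin_a, bin_b) if bin_a <= bin_b else (bin_b, bin_a)


# Column indices (0-based) into the BEDPE-like table; remap for caller-native
# layouts via the ``columns`` argument of read_interactions.
BEDPE_COLUMNS = {
    "chrom_a": 0, "start_a": 1, "end_a": 2,
    "chrom_b": 3, "start_b": 4, "end_b": 5,
    "count": 6, "p_value": 7,
}


def read_interactions(
    source,
    resolution: int = DEFAULT_RESOLUTION,
    columns: dict | None = None,
) -> list[InteractionRecord]:
    """Parse a BEDPE-like interaction table (two bins + count + raw P)."""
    cols = dict(BEDPE_COLUMNS)
    if columns:
        cols.update(columns)
    needed = max(cols.values()) + 1
    out: list[InteractionRecord] = []
    with _as_text_stream(source) as stream:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < needed:
                raise BedParseError(f"line {lineno}: expected >= {needed} columns")
            try:
                bin_a = pos_to_bin(fields[cols["chrom_a"]], int(fields[cols["start_a"]]), resolution)
                bin_b = pos_to_bin(fields[cols["chrom_b"]], int(fields[cols["start_b"]]), resolution)
                record = InteractionRecord(
                    bin_a, bin_b,
                    read_count=int(fields[cols["count"]]),
                    p_value=float(fields[cols["p_value"]]),
                )
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
            out.append(record)
    return out


def write_interactions(records: Iterable[InteractionRecord], destination) -> None:
    """Write records as BEDPE + count + raw P + adjusted P (``.`` if unset)."""
    own = not hasattr(destination, "write")
    stream = open(destination, "wt") if own else destination
    try:
        for r in records:
            adj = "." if r.adj_p is None else format(r.adj_p, ".6g")
            stream.write(
                f"{r.bin_a.chrom}\t{r.bin_a.start}\t{r.bin_a.end}\t"
                f"{r.bin_b.chrom}\t{r.bin_b.start}\t{r.bin_b.end}\t"
                f"{r.read_count}\t{r.p_value:.6g}\t{adj}\n"
            )
    finally:
        if own:
            stream.close()


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class FilterSummary:
    """Attrition bookkeeping for :func:`filter_interactions`."""

    n_input: int = 0
    n_inter_chromosomal: int = 0
    n_fail_adj_p: int = 0
    n_fail_count: int = 0
    n_fail_distance: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_interactions(
    records: Sequence[InteractionRecord],
    alpha: float = DEFAULT_ALPHA,
    min_count: int = DEFAULT_MIN_COUNT,
    min_bin_distance: int = DEFAULT_MIN_BIN_DISTANCE,
) -> tuple[list[InteractionRecord], FilterSummary]:
    """Apply the post-caller filters and return (kept records, summary).

    BH adjustment is computed jointly over all intra-chromosomal records
    (one family per table).  A record is kept iff adjusted P < ``alpha``,
    read count >= ``min_count`` and the distance between anchor bin starts
    is strictly greater than ``min_bin_distance`` (so same-bin and
    adjacent-bin pairs at matching resolution are excluded).
    Inter-chromosomal records are dropped with a logged count.
    Failure counts are tallied per criterion without short-circuiting.
    """
    summary = FilterSummary(n_input=len(records))
    if not records:
        return [], summary
    resolutions = {r.bin_a.resolution for r in records}
    if len(resolutions) > 1:
        raise ValueError(f"mixed resolutions in one table: {sorted(resolutions)}")
    intra = [r for r in records if r.intra_chromosomal]
    summary.n_inter_chromosomal = len(records) - len(intra)
    if summary.n_inter_chromosomal:
        logger.info("dropped %d inter-chromosomal records", summary.n_inter_chromosomal)
    if not intra:
        return [], summary
    adj = bh_adjust([r.p_value for r in intra])
    kept: list[InteractionRecord] = []
    for record, adj_p in zip(intra, adj):
        record = replace(record, adj_p=float(adj_p))
        ok = True
        if not record.adj_p < alpha:
            summary.n_fail_adj_p += 1
            ok = False
        if record.read_count < min_count:
            summary.n_fail_count += 1
            ok = False
        if not record.bin_distance > min_bin_distance:
            summary.n_fail_distance += 1
            ok = False
        if ok:
            kept.append(record)
    summary.n_kept = len(kept)
    return kept, summary


def anchor_index(records: Iterable[InteractionRecord]) -> IntervalIndex:
    """Interval index over every anchor bin of the given records; the
    indexed intervals carry the bin coordinates, one entry per (record,
    anchor)."""
    index = IntervalIndex()
    for r in records:
        for b in (r.bin_a, r.bin_b):
            index.add(GenomicInterval(b.chrom, b.start, b.end, name=f"{b.chrom}:{b.index}"))
    return index


def partners_of(region: GenomicInterval, records: Iterable[InteractionRecord]) -> list[GenomicBin]:
    """All bins contacted by a region: the *other* anchor of every record
    with one anchor overlapping ``region``.  Symmetric, deduplicated,
    sorted."""
    partners: set[GenomicBin] = set()
    for r in records:
        a_hit = _bin_overlaps(region, r.bin_a)
        b_hit = _bin_overlaps(region, r.bin_b)
        if a_hit:
            partners.add(r.bin_b)
        if b_hit:
            partners.add(r.bin_a)
    return sorted(partners)


def _bin_overlaps(region: GenomicInterval, b: GenomicBin) -> bool:
    return region.chrom == b.chrom and region.start < b.end and b.start < region.end
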