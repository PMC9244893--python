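"""ATAC-seq peak handling: MACS2 narrowPeak parsing and collapsing of peak
summits from multiple samples into a non-redundant set of fixed-width
open-chromatin peaks.

Summits from all samples (e.g. resting and stimulated cells, several
donors) are pooled, each extended 249 bp upstream and 250 bp downstream to
a 500 bp window, and conflicts are resolved iteratively: within any set of
mutually overlapping extended windows only the most significant summit
survives.  The iterative removal procedure has the same fixed point as a
greedy pass in descending significance, which is how it is implemented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from snplink.intervals import GenomicInterval, IntervalIndex, _as_text_stream, BedParseError

logger = logging.getLogger(__name__)

# Default extension: 249 bp upstream + summit base + 250 bp downstream = 500 bp.
UPSTREAM = 249
DOWNSTREAM = 250


@dataclass(frozen=True)
class PeakSummit:
    """A MACS2 peak summit with its significance (-log10 p by default)."""

    chrom: str
    summit_pos: int
    significance: float
    sample_label: str = ""

    def __post_init__(self) -> None:
        if self.summit_pos < 0:
            raise ValueError(f"negative summit position {self.summit_pos}")
        if not (self.significance == self.significance):  # NaN guard
            raise ValueError("significance must be finite")


@dataclass(frozen=True)
class CollapsedPeak:
    """A retained fixed-width peak; ``clipped`` marks summits too close to the
    chromosome start to extend fully (width < 500)."""

    interval: GenomicInterval
    summit: PeakSummit
    clipped: bool = False

    @property
    def significance(self) -> float:
        return self.summit.significance


def read_narrowpeak(source, significance_column: int = 8) -> list[PeakSummit]:
    """Parse an ENCODE 10-column narrowPeak file into summits.

    Column 10 is the summit offset from the interval start; ``-1`` means no
    summit was called and the interval midpoint is used.  ``significance_column``
    selects the MACS2 score used for conflict resolution: 8 (-log10 p,
    default) or 9 (-log10 q), 1-based as in the narrowPeak docs.
    """
    if significance_column not in (7, 8, 9):
        raise ValueError("significance_column must be 7, 8 or 9")
    out: list[PeakSummit] = []
    with _as_text_stream(source) as stream:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise BedParseError(
                    f"line {lineno}: narrowPeak requires 10 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                offset = int(fields[9])
                significance = float(fields[significance_column - 1])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
            if end <= start:
                raise BedParseError(f"line {lineno}: end <= start")
            summit = start + offset if offset >= 0 else start + (end - start) // 2
            out.append(PeakSummit(fields[0], summit, significance, sample_label=fields[3]))
    return out


def extend_summit(summit: PeakSummit, up: int = UPSTREAM, down: int = DOWNSTREAM) -> CollapsedPeak:
    """Extend a summit to ``[pos - up, pos + down + 1)``; clip at 0 if needed."""
    start = summit.summit_pos - up
    clipped = start < 0
    return CollapsedPeak(
        GenomicInterval(
            summit.chrom,
            max(start, 0),
            summit.summit_pos + down + 1,
            name=summit.sample_label or None,
            score=summit.significance,
        ),
        summit,
        clipped=clipped,
    )


def collapse_summits(
    summits,
    up: int = UPSTREAM,
    down: int = DOWNSTREAM,
) -> list[CollapsedPeak]:
    """Collapse pooled summits into non-overlapping fixed-width peaks.

    Greedy in descending significance: a summit's extended window is
    retained iff it overlaps no already-retained window.  Ties are broken
    by leftmost summit, then sample label, so the result is deterministic
    and independent of input order.  Clipped (chromosome-start) peaks keep
    their reduced width and still take part in conflict resolution.
    """
    candidates = [extend_summit(s, up, down) for s in summits]
    candidates.sort(
        key=lambda p: (-p.significance, p.summit.chrom, p.summit.summit_pos, p.summit.sample_label)
    )
    retained: list[CollapsedPeak] = []
    index = IntervalIndex()
    n_clipped = 0
    for peak in candidates:
        if not index.any_overlap(peak.interval):
            retained.append(peak)
            index.add(peak.interval)
            if peak.clipped:
                n_clipped += 1
    if n_clipped:
        logger.warning("%d retained peaks clipped at a chromosome start (width < %d)",
                       n_clipped, up + down + 1)
    retained.sort(key=lambda p: p.interval.sort_key())
    return retained
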