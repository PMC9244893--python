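"""Promoter/enhancer annotation built from three sources:

* gene-model TSSs extended 2 kb upstream (promoters),
* chromHMM 15-state segmentations, with TssA/TssAFlnk/TssBiv/BivFlnk
  mapped to promoters and EnhG/Enh/EnhBiv to enhancers,
* FANTOM5 bidirectionally-transcribed enhancers (any BED).

Each class is merged separately into a non-redundant interval set; raw
elements are retained so that per-variant reports can say *which* source
(chromHMM state label, FANTOM5 flag) supports an overlap.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from snplink.intervals import (
    BedParseError,
    GenomicInterval,
    IntervalIndex,
    _as_text_stream,
    merge,
)

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 2000

# 15-state chromHMM (Roadmap core model) mnemonics.
CHROMHMM_STATES = {
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
}
PROMOTER_STATES = {"TssA", "TssAFlnk", "TssBiv", "BivFlnk"}
ENHANCER_STATES = {"EnhG", "Enh", "EnhBiv"}

_STATE_PREFIX = re.compile(r"^\d+_")


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand and name; the TSS is the start for ``+``
    genes and ``end - 1`` for ``-`` genes."""

    interval: GenomicInterval
    gene_name: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_name!r} needs a +/- strand")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass(frozen=True)
class RegulatoryElement:
    """An interval carrying a class (promoter/enhancer) and its source."""

    interval: GenomicInterval
    element_class: str  # "promoter" | "enhancer"
    source: str  # "TSS" | "chromHMM" | "FANTOM5"
    state_label: str | None = None

    def __post_init__(self) -> None:
        if self.element_class not in ("promoter", "enhancer"):
            raise ValueError(f"unknown element class {self.element_class!r}")
        if self.source not in ("TSS", "chromHMM", "FANTOM5"):
            raise ValueError(f"unknown source {self.source!r}")


def read_genes(source) -> list[GeneModel]:
    """Read a gene-model TSV: chrom, start, end, strand, name (0-based
    half-open, header lines starting with '#' skipped)."""
    out: list[GeneModel] = []
    with _as_text_stream(source) as stream:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise BedParseError(f"line {lineno}: expected 5 columns (chrom, start, end, strand, name)")
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), strand=fields[3], name=fields[4]
                )
                out.append(GeneModel(iv, fields[4]))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return out


def strip_state_prefix(label: str) -> str:
    """``"7_Enh"`` -> ``"Enh"``; labels without a numeric prefix pass through."""
    return _STATE_PREFIX.sub("", label)


def promoters_from_tss(
    genes: Iterable[GeneModel],
    upstream: int = PROMOTER_UPSTREAM,
    include_tss: bool = False,
) -> list[RegulatoryElement]:
    """Promoter = the ``upstream`` bases 5' of each TSS.

    Read literally, "upstream of the TSS" excludes the TSS base itself:
    a ``+`` gene with TSS t gets ``[t - upstream, t)`` and a ``-`` gene
    ``[t + 1, t + 1 + upstream)``.  ``include_tss=True`` widens each window
    by the TSS base.  Windows are clipped at the chromosome start.
    """
    out: list[RegulatoryElement] = []
    n_clipped = 0
    for gene in genes:
        t = gene.tss
        if gene.strand == "+":
            start = t - upstream
            end = t + 1 if include_tss else t
        else:
            start = t if include_tss else t + 1
            end = t + 1 + upstream
        if start < 0:
            n_clipped += 1
            start = 0
        if end <= start:  # TSS at the very chromosome start
            n_clipped += 1
            continue
        out.append(
            RegulatoryElement(
                GenomicInterval(gene.chrom, start, end, strand=gene.strand, name=gene.gene_name),
                "promoter",
                "TSS",
            )
        )
    if n_clipped:
        logger.warning("%d promoter windows clipped at a chromosome start", n_clipped)
    return out


def classify_chromhmm(segments: Iterable[GenomicInterval]) -> list[RegulatoryElement]:
    """Map chromHMM segments (state mnemonic in the BED name column, with or
    without a numeric prefix) to promoter/enhancer elements.

    The seven promoter/enhancer states are emitted; the other eight states
    are dropped with logged counts; mnemonics outside the 15-state
    vocabulary are dropped with a warning.
    """
    out: list[RegulatoryElement] = []
    dropped: dict[str, int] = {}
    for seg in segments:
        label = strip_state_prefix(seg.name or "")
        if label in PROMOTER_STATES:
            out.append(RegulatoryElement(seg, "promoter", "chromHMM", state_label=label))
        elif label in ENHANCER_STATES:
            out.append(RegulatoryElement(seg, "enhancer", "chromHMM", state_label=label))
        elif label in CHROMHMM_STATES:
            dropped[label] = dropped.get(label, 0) + 1
        else:
            logger.warning("unknown chromHMM mnemonic %r dropped", seg.name)
    if dropped:
        logger.info("dropped non-regulatory chromHMM states: %s", dropped)
    return out


def fantom_enhancers(intervals: Iterable[GenomicInterval]) -> list[RegulatoryElement]:
    """Wrap FANTOM5 enhancer BED records as enhancer elements (taken as
    given; no expression re-thresholding)."""
    return [RegulatoryElement(iv, "enhancer", "FANTOM5") for iv in intervals]


class RegulatorySet:
    """Merged promoter and enhancer interval sets with source provenance.

    ``merged_promoters`` / ``merged_enhancers`` are the class-wise unions
    used for overlap tests; the raw elements stay queryable so reports can
    name the chromHMM state(s) and FANTOM5 support under any position.
    """

    def __init__(self, elements: Iterable[RegulatoryElement]):
        self.elements = list(elements)
        prom = [e.interval for e in self.elements if e.element_class == "promoter"]
        enh = [e.interval for e in self.elements if e.element_class == "enhancer"]
        self.merged_promoters: list[GenomicInterval] = merge(prom)
        self.merged_enhancers: list[GenomicInterval] = merge(enh)
        self._prom_index = IntervalIndex(self.merged_promoters)
        self._enh_index = IntervalIndex(self.merged_enhancers)
        self._element_index = IntervalIndex()
        for i, e in enumerate(self.elements):
            self._element_index.add(
                GenomicInterval(e.interval.chrom, e.interval.start, e.interval.end, name=str(i))
            )

    def in_promoter(self, query: GenomicInterval) -> bool:
        return self._prom_index.any_overlap(query)

    def in_enhancer(self, query: GenomicInterval) -> bool:
        return self._enh_index.any_overlap(query)

    def overlapping_elements(self, query: GenomicInterval) -> list[RegulatoryElement]:
        hits = self._element_index.overlapping(query)
        return [self.elements[int(h.name)] for h in hits]

    @property
    def all_merged(self) -> list[GenomicInterval]:
        """Union of both classes (for genome-coverage reporting)."""
        return merge(self.merged_promoters + self.merged_enhancers)


def build_regulatory_set(
    fantom: Sequence[GenomicInterval] = (),
    chromhmm_segments: Sequence[GenomicInterval] = (),
    genes: Sequence[GeneModel] = (),
    promoter_upstream: int = PROMOTER_UPSTREAM,
    include_tss: bool = False,
) -> RegulatorySet:
    """Assemble the merged promoter/enhancer annotation from all sources."""
    elements: list[RegulatoryElement] = []
    elements.extend(fantom_enhancers(fantom))
    elements.extend(classify_chromhmm(chromhmm_segments))
    elements.extend(promoters_from_tss(genes, upstream=promoter_upstream, include_tss=include_tss))
    return RegulatorySet(elements)
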