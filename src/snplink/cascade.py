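"""The four-criterion variant prioritisation cascade and variant-to-gene
linking.

A variant survives iff it

1. lies in an open-chromatin (ATAC-seq) peak,
2. lies inside an anchor bin of a significant, filtered Hi-C interaction,
3. overlaps a promoter or enhancer element, and
4. lies in a lineage transcription-factor binding peak (e.g. FOXP3).

All four flags are evaluated for every variant (no short-circuiting) so
per-criterion attrition is reportable.  Surviving variants are linked to
candidate target genes through the partner bins of the interactions they
anchor: a gene is a candidate target when its promoter (2 kb upstream of
the TSS) or gene body overlaps a partner bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from snplink.hic import GenomicBin, InteractionRecord, partners_of
from snplink.intervals import (
    GenomicInterval,
    IntervalIndex,
    NoNeighbourError,
    _as_text_stream,
    BedParseError,
    gap,
)
from snplink.regulatory import GeneModel, RegulatorySet, promoters_from_tss

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Variant:
    """A point substitution; ``pos`` is 0-based (converted from 1-based VCF
    coordinates at parse time)."""

    chrom: str
    pos: int
    ref: str = "N"
    alt: str = "N"
    rsid: str | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("negative position")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"MAF {self.maf} outside [0, 1]")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1, name=self.rsid)

    @property
    def display_pos(self) -> int:
        """1-based position for reports."""
        return self.pos + 1


@dataclass
class CascadeResult:
    """Per-variant outcome: the four criterion flags, regulatory context,
    3D partners and candidate target genes."""

    variant: Variant
    in_atac: bool = False
    in_hic_anchor: bool = False
    in_regulatory: bool = False
    in_tf_peak: bool = False
    element_context: str = "none"  # promoter | enhancer | both | none
    interacting_regions: list[GenomicBin] = field(default_factory=list)
    interacting_genes: list[str] = field(default_factory=list)
    nearest_gene: str | None = None
    nearest_distance: int | None = None
    chromhmm_states: list[str] = field(default_factory=list)
    fantom5: bool = False

    @property
    def passes(self) -> bool:
        return self.in_atac and self.in_hic_anchor and self.in_regulatory and self.in_tf_peak


def read_variants_tsv(source) -> list[Variant]:
    """Read a 4+-column variant TSV: chrom, 1-based pos, rsid, ref/alt pair
    (``A/G``), optional MAF in column 5."""
    out: list[Variant] = []
    with _as_text_stream(source) as stream:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: expected >= 4 columns")
            try:
                pos1 = int(fields[1])
                ref, _, alt = fields[3].partition("/")
                maf = float(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") else None
                out.append(
                    Variant(fields[0], pos1 - 1, ref=ref, alt=alt or "N",
                            rsid=fields[2] if fields[2] != "." else None, maf=maf)
                )
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return out


def read_variants_vcf(path) -> list[Variant]:
    """Read SNVs from a (sites-only acceptable) VCF via pysam; multi-allelic
    records are split, one Variant per alternate allele; non-SNV alleles are
    skipped with a logged count."""
    import pysam

    out: list[Variant] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt == "*":
                    n_skipped += 1
                    continue
                maf = None
                af = rec.info.get("AF")
                if af is not None:
                    af0 = af[0] if isinstance(af, tuple) else af
                    maf = min(float(af0), 1.0 - float(af0))
                out.append(
                    Variant(rec.chrom, rec.pos - 1, ref=rec.ref, alt=alt,
                            rsid=rec.id, maf=maf)
                )
    if n_skipped:
        logger.info("skipped %d non-SNV alleles", n_skipped)
    return out


def classify_element_context(variant: Variant, regulatory: RegulatorySet) -> str:
    """promoter / enhancer / both / none, from the class-separated merged
    sets.  "both" is the mixed case of a variant under a promoter-class
    chromHMM state *and* an enhancer annotation."""
    iv = variant.interval
    in_p = regulatory.in_promoter(iv)
    in_e = regulatory.in_enhancer(iv)
    if in_p and in_e:
        return "both"
    if in_p:
        return "promoter"
    if in_e:
        return "enhancer"
    return "none"


def context_from_labels(chromhmm_state: str | None, fantom5: bool) -> str:
    """Label-level context classification, for annotation tables that carry
    a chromHMM mnemonic and a FANTOM5 flag instead of coordinates."""
    from snplink.regulatory import ENHANCER_STATES, PROMOTER_STATES, strip_state_prefix

    state = strip_state_prefix(chromhmm_state) if chromhmm_state else None
    in_p = state in PROMOTER_STATES
    in_e = (state in ENHANCER_STATES) or fantom5
    if in_p and in_e:
        return "both"
    if in_p:
        return "promoter"
    if in_e:
        return "enhancer"
    return "none"


def gene_region_index(genes: Sequence[GeneModel], promoter_upstream: int = 2000,
                      use_promoter: bool = True, use_body: bool = True) -> IntervalIndex:
    """Index of gene-associated regions (promoter windows and/or bodies),
    each carrying the gene name, used to assign genes to partner bins."""
    index = IntervalIndex()
    if use_body:
        for g in genes:
            iv = g.interval
            index.add(GenomicInterval(iv.chrom, iv.start, iv.end, name=g.gene_name))
    if use_promoter:
        for e in promoters_from_tss(genes, upstream=promoter_upstream):
            iv = e.interval
            index.add(GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.name))
    return index


def link_target_genes(
    result: CascadeResult,
    interactions: Sequence[InteractionRecord],
    genes: Sequence[GeneModel],
    gene_index: IntervalIndex | None = None,
) -> CascadeResult:
    """Fill ``interacting_regions``/``interacting_genes`` for a variant in a
    Hi-C anchor; no-op (empty lists) otherwise."""
    if not result.in_hic_anchor:
        result.interacting_regions = []
        result.interacting_genes = []
        return result
    if gene_index is None:
        gene_index = gene_region_index(genes)
    partners = partners_of(result.variant.interval, interactions)
    names: set[str] = set()
    for b in partners:
        for hit in gene_index.overlapping(b.interval):
            if hit.name:
                names.add(hit.name)
    result.interacting_regions = partners
    result.interacting_genes = sorted(names)
    return result


def annotate_nearest(variant: Variant, genes: Sequence[GeneModel]) -> tuple[str, int]:
    """Closest gene body by linear distance (0 when the variant is inside
    the body); ties broken by smaller TSS distance, then gene name."""
    same = [g for g in genes if g.chrom == variant.chrom]
    if not same:
        raise NoNeighbourError(f"no gene on chromosome {variant.chrom!r}")
    iv = variant.interval

    def key(g: GeneModel):
        return (gap(iv, g.interval), abs(variant.pos - g.tss), g.gene_name)

    best = min(same, key=key)
    return best.gene_name, gap(iv, best.interval)


def run_cascade(
    variants: Sequence[Variant],
    atac_peaks: Sequence[GenomicInterval],
    interactions: Sequence[InteractionRecord],
    regulatory: RegulatorySet,
    tf_peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel] = (),
    link_genes: bool = True,
) -> list[CascadeResult]:
    """Evaluate all four criteria for every variant, then link passing
    variants (and any variant in a Hi-C anchor) to partner regions and
    candidate target genes.

    ``interactions`` must already be post-caller filtered
    (:func:`snplink.hic.filter_interactions`).  Empty filter inputs yield
    an all-false flag for that criterion with a warning, never an error.
    Result order follows (chrom, pos) of the input variants.
    """
    for label, collection in (("ATAC peaks", atac_peaks), ("Hi-C interactions", interactions),
                              ("regulatory elements", regulatory.elements), ("TF peaks", tf_peaks)):
        if not collection:
            logger.warning("empty filter input: %s — that criterion fails for every variant", label)

    atac_index = IntervalIndex(atac_peaks)
    tf_index = IntervalIndex(tf_peaks)
    from snplink.hic import anchor_index as build_anchor_index

    anchors = build_anchor_index(interactions)
    gene_index = gene_region_index(genes) if genes else IntervalIndex()

    results: list[CascadeResult] = []
    for variant in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        iv = variant.interval
        r = CascadeResult(
            variant=variant,
            in_atac=atac_index.any_overlap(iv),
            in_hic_anchor=anchors.any_overlap(iv),
            in_regulatory=regulatory.in_promoter(iv) or regulatory.in_enhancer(iv),
            in_tf_peak=tf_index.any_overlap(iv),
        )
        r.element_context = classify_element_context(variant, regulatory)
        hits = regulatory.overlapping_elements(iv)
        r.chromhmm_states = sorted({e.state_label for e in hits if e.state_label})
        r.fantom5 = any(e.source == "FANTOM5" for e in hits)
        if link_genes and r.in_hic_anchor:
            link_target_genes(r, interactions, genes, gene_index=gene_index)
        if genes:
            try:
                r.nearest_gene, r.nearest_distance = annotate_nearest(variant, genes)
            except NoNeighbourError:
                pass
        results.append(r)
    return results


def attrition_summary(results: Sequence[CascadeResult]) -> dict:
    """Counts entering and surviving each criterion, plus the passing set."""
    return {
        "n_input": len(results),
        "n_in_atac": sum(r.in_atac for r in results),
        "n_in_hic_anchor": sum(r.in_hic_anchor for r in results),
        "n_in_regulatory": sum(r.in_regulatory for r in results),
        "n_in_tf_peak": sum(r.in_tf_peak for r in results),
        "n_pass": sum(r.passes for r in results),
    }


REPORT_COLUMNS = [
    "chrom", "pos", "rsid", "nearest_locus", "nearest_distance",
    "chromhmm_states", "fantom5", "element_context", "interacting_genes",
]


def tabulate(results: Iterable[CascadeResult]) -> pd.DataFrame:
    """One row per *passing* variant, in (chrom, pos) order, with 1-based
    display coordinates — the per-variant report table."""
    rows = []
    for r in sorted((r for r in results if r.passes),
                    key=lambda r: (r.variant.chrom, r.variant.pos)):
        rows.append({
            "chrom": r.variant.chrom,
            "pos": r.variant.display_pos,
            "rsid": r.variant.rsid or ".",
            "nearest_locus": r.nearest_gene or ".",
            "nearest_distance": r.nearest_distance if r.nearest_distance is not None else ".",
            "chromhmm_states": ",".join(r.chromhmm_states) or ".",
            "fantom5": "yes" if r.fantom5 else "no",
            "element_context": r.element_context,
            "interacting_genes": ",".join(r.interacting_genes) or ".",
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
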