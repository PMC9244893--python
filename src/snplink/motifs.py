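"""Allele-specific PWM scoring: how much does swapping the reference for
the alternative allele change the best log-odds motif score?

The score of a window is the standard PWM log-odds in bits,
``sum_i log2(p_i(base_i) / bg(base_i))`` with pseudocount-regularised
probabilities.  For a variant, each allele is substituted into its genomic
context and the score maximised over every motif placement covering the
variant position, on both strands (reverse-complement scanning).  A
negative delta (alt - ref) predicts loss of binding for the alternative
allele.  Scoring is typically restricted to variants inside TF footprints
that also carry ChIP evidence (:func:`footprint_filter`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from snplink.cascade import Variant
from snplink.intervals import GenomicInterval, IntervalIndex

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DEFAULT_PSEUDOCOUNT = 0.8  # total pseudocount per column, split by background


class AmbiguousBaseError(ValueError):
    """Raised when a window contains a base outside {A, C, G, T}."""


@dataclass(frozen=True)
class PWM:
    """A position probability matrix over {A, C, G, T} with its background.

    ``matrix`` holds the pseudocount-regularised probabilities (L x 4,
    rows sum to 1); build from raw counts with :meth:`from_counts` or from
    JASPAR text with :meth:`read_jaspar`.
    """

    motif_id: str
    matrix: tuple  # L x 4 nested tuples, hashable
    background: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("matrix must be L x 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(sum(self.background), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    ) -> "PWM":
        """Counts (L x 4) -> probabilities with a background-weighted
        pseudocount: ``p = (n + pc*bg) / (N + pc)``."""
        c = np.asarray(counts, dtype=float)
        bg = np.asarray(background, dtype=float)
        probs = (c + pseudocount * bg) / (c.sum(axis=1, keepdims=True) + pseudocount)
        return cls(motif_id, tuple(map(tuple, probs)), tuple(bg))

    def reverse_complement(self) -> "PWM":
        rc = self.array[::-1, ::-1]
        bg = np.asarray(self.background)[::-1]
        return PWM(self.motif_id, tuple(map(tuple, rc)), tuple(bg))


def read_jaspar(source, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Parse JASPAR-format (pfm/jaspar text) count matrices into PWMs.

    Parsing is delegated to Bio.motifs; count-to-probability conversion
    with the background-weighted pseudocount is done here so the scoring
    convention is uniform.
    """
    from Bio import motifs as bio_motifs

    own = not hasattr(source, "read")
    handle = open(source) if own else source
    try:
        parsed = bio_motifs.parse(handle, "jaspar")
        out = []
        for m in parsed:
            counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
            name = m.matrix_id or m.name or "motif"
            out.append(PWM.from_counts(str(name), counts, pseudocount=pseudocount))
        return out
    finally:
        if own:
            handle.close()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def score_window(sequence: str, pwm: PWM) -> float:
    """Log2-odds score of one window of length ``len(pwm)``.

    Raises :class:`AmbiguousBaseError` for non-ACGT bases so callers can
    skip and flag the window.
    """
    seq = sequence.upper()
    if len(seq) != len(pwm):
        raise ValueError(f"window length {len(seq)} != motif length {len(pwm)}")
    m = pwm.array
    bg = pwm.background
    score = 0.0
    for i, base in enumerate(seq):
        j = _BASE_INDEX.get(base)
        if j is None:
            raise AmbiguousBaseError(f"ambiguous base {base!r} at window offset {i}")
        score += np.log2(m[i, j] / bg[j])
    return float(score)


def best_allele_score(
    context_sequence: str,
    variant_offset: int,
    allele: str,
    pwm: PWM,
) -> tuple[float, int, str]:
    """Best (score, placement offset, strand) over every motif placement
    covering the variant, with ``allele`` substituted at ``variant_offset``.

    The placement offset is relative to the context start, on the forward
    coordinate system for both strands.  The context must cover at least
    L-1 bases on each side of the variant.  Windows containing ambiguous
    bases are skipped; if every placement is ambiguous an
    :class:`AmbiguousBaseError` propagates.
    """
    L = len(pwm)
    if variant_offset < 0 or variant_offset >= len(context_sequence):
        raise ValueError("variant offset outside context")
    if variant_offset < L - 1 or len(context_sequence) - variant_offset < L:
        raise ValueError(f"context too short: need {L - 1} flanking bases each side")
    if len(allele) != 1:
        raise ValueError("only single-base alleles are scored")
    seq = context_sequence[:variant_offset] + allele.upper() + context_sequence[variant_offset + 1:]
    rc_pwm = pwm.reverse_complement()
    best: tuple[float, int, str] | None = None
    n_skipped = 0
    for offset in range(variant_offset - L + 1, variant_offset + 1):
        window = seq[offset: offset + L]
        for strand, matrix in (("+", pwm), ("-", rc_pwm)):
            try:
                s = score_window(window, matrix)
            except AmbiguousBaseError:
                n_skipped += 1
                continue
            if best is None or s > best[0] or (s == best[0] and (offset, strand) < best[1:]):
                best = (s, offset, strand)
    if best is None:
        raise AmbiguousBaseError(f"all {n_skipped} windows contained ambiguous bases")
    return best


@dataclass(frozen=True)
class AlleleDelta:
    """Allele-specific binding change for one variant x motif pair.

    ``delta = best_alt_score - best_ref_score`` in bits; negative predicts
    reduced binding of the alternative allele.
    """

    variant: Variant
    motif_id: str
    best_ref_score: float
    best_alt_score: float
    ref_placement: tuple[int, str]
    alt_placement: tuple[int, str]

    @property
    def delta(self) -> float:
        return self.best_alt_score - self.best_ref_score


def delta_binding(variant: Variant, context_sequence: str, variant_offset: int,
                  pwm: PWM) -> AlleleDelta:
    """Score both alleles of a variant in its sequence context.

    ``context_sequence`` carries the *reference* sequence around the
    variant; ``variant_offset`` is the variant's position within it.
    """
    ref_s, ref_off, ref_strand = best_allele_score(context_sequence, variant_offset,
                                                   variant.ref, pwm)
    alt_s, alt_off, alt_strand = best_allele_score(context_sequence, variant_offset,
                                                   variant.alt, pwm)
    return AlleleDelta(variant, pwm.motif_id, ref_s, alt_s,
                       (ref_off, ref_strand), (alt_off, alt_strand))


def context_from_fasta(fasta_path, variant: Variant, flank: int):
    """Extract ``2*flank + 1`` reference bases centred on the variant from
    an indexed FASTA; returns (sequence, offset-of-variant-in-sequence)."""
    from pyfaidx import Fasta

    with Fasta(str(fasta_path)) as fa:
        chrom = fa[variant.chrom]
        start = max(variant.pos - flank, 0)
        end = min(variant.pos + flank + 1, len(chrom))
        seq = str(chrom[start:end])
    return seq, variant.pos - start


def footprint_filter(
    variants: Sequence[Variant],
    footprints: Sequence[GenomicInterval],
    tf_peaks: Sequence[GenomicInterval],
) -> list[Variant]:
    """Variants inside both a TF footprint and a TF ChIP peak — the entry
    point for motif scoring."""
    fp_index = IntervalIndex(footprints)
    tf_index = IntervalIndex(tf_peaks)
    return [v for v in variants
            if fp_index.any_overlap(v.interval) and tf_index.any_overlap(v.interval)]
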