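# Methods

This document describes the model implemented by `snplink`, the
parameter defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the known limitations.

## 1. Coordinate conventions

All internal coordinates are **0-based, half-open** (`[start, end)`),
the native BED convention.  Conversion to 1-based coordinates happens
only at interface boundaries: VCF/TSV variant input (1-based positions
are decremented on read) and report tables (`pos` is emitted 1-based as
`display_pos`).  Chromosome names are treated as opaque strings and
never renamed; inputs with mixed naming schemes (`chr1` vs `1`) will
simply fail to intersect, which is deliberate — silent renaming hides
genome-build mismatches.

## 2. The four-criterion cascade

A variant is prioritised when its single-base interval intersects all
four of the following, computed independently (no short-circuiting, so
attrition can be reported per criterion):

1. **Open chromatin** — the non-redundant collapsed ATAC peak set (§3).
2. **Chromatin-contact anchor** — any bin of a filtered Hi-C
   interaction (§4).
3. **Regulatory element** — the merged promoter or enhancer set (§5).
4. **TF binding** — a ChIP-seq peak of the chosen lineage-defining
   factor, taken as provided.

Element context is classified as `promoter`, `enhancer`, `both` or
`none` from the merged class sets.  The cascade is a pure intersection:
applying the four single-criterion filters in any order and
intersecting gives exactly the passing set, and adding intervals to any
input can only grow it.  Both properties are asserted in the test
suite.

**Gene linking.**  For each passing variant, the partner bins of every
filtered interaction touching the variant's bin are collected, and a
gene is linked if its body *or* its promoter window overlaps a partner
bin.  The nearest gene (by gap distance; ties broken by TSS distance,
then name) is reported separately so that "nearest" and "interacting"
can disagree — the disagreement is the scientifically interesting case.

## 3. ATAC peak collapsing

MACS2 summit calls from multiple samples are reduced to a non-redundant
fixed-width peak set.  Each summit is extended to a 500 bp window
(summit − 249 to summit + 250, half-open), matching a nucleosome-scale
accessible region.  Windows are then collapsed iteratively: the most
significant remaining summit is retained and every summit whose window
overlaps the retained window is discarded, until no summits remain.
Ties in significance are broken by leftmost summit, then sample label,
making the procedure deterministic and input-order independent.
Windows that would extend past the chromosome start are clipped and
flagged.  The implementation is greedy over a sorted list with an
interval index; the test suite checks it against a literal O(n²)
restatement of the iterative definition.

## 4. Hi-C interaction filtering

Interactions are read as bin pairs at a fixed resolution (default
5 kb; `bin = floor(pos / resolution)`), with raw read counts and
p-values from an upstream interaction caller.  Filtering applies, in
order and with per-step attrition counts:

* inter-chromosomal records are dropped (and logged) — the workflow is
  about *cis*-regulatory contacts;
* Benjamini–Hochberg adjustment over **all intra-chromosomal records
  jointly** (via `statsmodels`), then `adj_p < 0.05`;
* supporting read count ≥ 5, excluding contacts supported by a handful
  of read pairs;
* bin-centre distance strictly greater than one bin (5 kb), removing
  adjacent-bin records whose counts are dominated by linear genomic
  proximity rather than looping.

Filtering is idempotent and order-stable; records are canonically
oriented (lower bin first) on construction.

## 5. Regulatory element sets

Three sources are merged into two element classes:

* **TSS promoters** — 2 kb strictly upstream of each TSS.  For a
  `+`-strand gene with TSS at `t`: `[t − 2000, t)`; for `−` strand:
  `[t + 1, t + 2001)`.  The TSS base itself is excluded by default
  (`include_tss=True` widens the window by one base).  Windows are
  clipped at chromosome start.
* **chromHMM 15-state segments** — states are mapped to classes:
  promoters = {TssA, TssAFlnk, TssBiv, BivFlnk}, enhancers = {EnhG,
  Enh, EnhBiv}.  The remaining eight states are dropped with counts;
  unknown mnemonics are dropped with a warning.  Numeric prefixes
  (`7_Enh`) are stripped.
* **FANTOM5 enhancers** — taken as given.

Each class is merged (union of abutting/overlapping intervals)
separately; the original elements are retained alongside the merged
sets so overlap queries can report provenance (which source, which
state) rather than only a class label.

## 6. Statistics

**Gene-set overlap** uses Fisher's exact test (one-sided by default) on
the 2×2 table of disease genes × TF-bound genes within a stated gene
universe; inputs must be subsets of the universe.  The implementation
wraps `scipy.stats.fisher_exact`; the tests verify it against a full
enumeration of the hypergeometric distribution over fixed margins.

**Whole-workflow permutation test.**  To ask whether an observed
variant set is unusually enriched for cascade passes, each of `n_perm`
permutations draws `|observed|` variants without replacement from a
user-supplied background pool, runs the *entire* cascade on the drawn
set, and compares pass counts with a one-sided Fisher test on
`[[obs_pass, obs_fail], [perm_pass, perm_fail]]`.  Reported are the
mean per-permutation P and an empirical rank P,
`(1 + #{perm_pass ≥ obs_pass}) / (n_perm + 1)`, which cannot be zero.
Note the discrete floor: with `k` observed and `k` permuted variants
the smallest achievable per-permutation P is `1 / C(2k, k)`
(≈ 0.004 for k = 5).  Randomness uses `numpy.random.default_rng(seed)`
only; results are bit-reproducible given the seed.

**Multiple testing** uses Benjamini–Hochberg throughout (via
`statsmodels`), verified against the textbook step-up formula.

## 7. Allele-specific motif scoring

PWMs are built from count matrices with a pseudocount proportional to
background: `p = (count + 0.8·bg) / (N + 0.8)` with uniform `bg =
0.25` (the conventional JASPAR-style correction; 0.8 spreads one
pseudo-observation over the four bases).  A window of length `L`
scores `Σ log2(p_i(base) / bg)` bits; ambiguous bases raise an error
rather than being scored silently.  For a variant, every placement of
the motif covering the variant base is scored on both strands for each
allele; the per-allele best scores are compared and
`delta = best_alt − best_ref` reported.  Delta is antisymmetric under
allele swap and invariant under reverse-complementing the context
(both tested).  An optional entry filter restricts scoring to variants
inside both a TF footprint and a TF ChIP peak.  Sequence context is
pulled from an indexed FASTA via `pyfaidx`.

## 8. Synthetic data generator

`snplink.fixtures` generates a complete input bundle (genome sizes,
FASTA, genes, chromHMM segments, FANTOM5 enhancers, ATAC summits, TF
peaks, footprints, interaction table, variants) plus a machine-readable
`truth.json`, byte-identical for a given seed.

**What it emulates.**  Distance-dependent Hi-C contact noise: for each
intra-chromosomal bin pair, an expected count `mu = amplitude ·
separation^(−decay_exponent)` (power-law distance decay), an observed
Poisson draw, and a Poisson upper-tail p-value as a stand-in for an
interaction caller.  Planted contacts have their expectation inflated
(×10, floored at mu = 30) so they survive BH at the default depth.
Realistic file formats (narrowPeak, BED, BEDPE-like, FASTA, VCF-like
TSV) are emitted so the same readers run on synthetic and real data.

**Planted truth by construction.**  The chromosome is zoned: planted
variants and their features occupy the first 40%, background features
are confined to the last 50%, so labels hold for every seed without
per-seed tuning.  Pass-all variants sit mid-bin in an anchor bin with a
partner bin four bins away containing the target gene; each near-miss
variant is complete except for exactly one named criterion (cycling
ATAC / Hi-C / regulatory / TF), which is what lets tests assert *which*
criterion failed.

**What it does not emulate.**  Real genome scale (megabase
chromosomes, not gigabases), realistic gene density or GC content,
ATAC/ChIP read-level noise (peaks are planted as intervals, not called
from reads), biological replicate structure, linkage disequilibrium
between variants, or the empirical distributions of real Hi-C matrices
(TADs, compartments, ICE normalisation).  Quantities measured on
synthetic data — recall, calibration — validate the *implementation*,
not biological effect sizes.

## 9. Parameter defaults

| parameter | default | rationale |
|---|---|---|
| peak width | 500 bp (−249/+250) | nucleosome-scale accessible region around a summit |
| Hi-C resolution | 5 kb | fine enough to separate promoters from nearby enhancers |
| adjusted α | 0.05 | conventional FDR level, applied after joint BH |
| min read count | 5 | removes contacts supported by a handful of pairs |
| min bin distance | > 5 kb (strict) | excludes adjacent bins dominated by linear proximity |
| promoter window | 2 kb upstream, TSS excluded | common promoter definition; strictness documented in §5 |
| PWM pseudocount | 0.8 × bg | conventional JASPAR-style correction |
| MAF threshold (`--common-only`) | > 0.1 | restricts to common variants when requested |
| permutations | 100 (CLI default) | balance of resolution vs runtime; rank P floor 1/(n+1) |

All thresholds are overridable per call and via the CLI's YAML config;
every CLI run writes the thresholds used (and SHA-256 hashes of all
inputs) into a manifest next to its output.

## 10. Limitations

* The cascade is a hard intersection: a variant missing any one data
  type is dropped, so sensitivity is bounded by the weakest assay, and
  absence of evidence (e.g. a shallow ATAC library) reads as evidence
  of absence.
* Gene linking is bin-resolution: any gene overlapping a 5 kb partner
  bin is linked, which can over-link in gene-dense regions and cannot
  distinguish genes within one bin.
* The promoter definition (2 kb strictly upstream) is one of several
  reasonable conventions; downstream-inclusive definitions will
  classify some variants differently.
* Fisher's exact test on permutation pass counts treats variants as
  exchangeable; correlated variants (LD blocks) violate this and make
  the test anti-conservative on real data — choose the background pool
  accordingly (e.g. LD-pruned).
* The worked-example table is a curated record set shipped for
  demonstration and summary-statistics testing; the package does not
  ship the genome-scale assay data needed to regenerate it from raw
  inputs.
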