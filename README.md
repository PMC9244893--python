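# snplink

Prioritise non-coding GWAS variants using cell-type-specific chromatin
data, and link the survivors to the genes they physically contact.

Most disease-associated variants from genome-wide association studies
fall outside protein-coding sequence, and fine-mapping typically leaves
dozens of statistically indistinguishable candidates per locus.  Which
of them actually do something, and in which cell type?  `snplink`
implements an intersection-based answer for one cell type at a time: a
variant is kept only if, in that cell type, it lies

1. inside **open chromatin** (a non-redundant ATAC-seq peak set),
2. inside the **anchor bin of a significant Hi-C chromatin contact**,
3. inside a **regulatory element** (promoter or enhancer, from TSS
   windows, chromHMM segmentation and FANTOM5 enhancers), and
4. inside a **binding site of a lineage-defining transcription factor**
   (e.g. FOXP3 for regulatory T cells).

Variants passing all four criteria are then connected to candidate
target genes through the partner bins of their chromatin contacts —
often revealing genes tens or hundreds of kilobases away from the
variant, rather than simply the nearest gene.

The package also provides the supporting statistics (Fisher's exact
gene-set overlap, a whole-workflow permutation test), allele-specific
PWM scoring to ask whether a prioritised variant strengthens or weakens
a motif match, and a deterministic synthetic-data generator with planted
ground truth for end-to-end validation.

## Quick start

```python
from snplink.cascade import run_cascade, tabulate, attrition_summary
from snplink.fixtures import FixtureSpec, generate, load_bundle

bundle = generate(FixtureSpec(seed=42), "demo")   # synthetic inputs + truth
data = load_bundle("demo")

results = run_cascade(
    data["variants"], data["collapsed_peaks"], data["interactions"],
    data["regulatory"], data["tf_peaks"], genes=data["genes"],
)
print(attrition_summary(results))
print(tabulate(results).to_string(index=False))
```

which prints (exactly, for seed 42):

```
{'n_input': 60, 'n_in_atac': 13, 'n_in_hic_anchor': 8, 'n_in_regulatory': 15, 'n_in_tf_peak': 9, 'n_pass': 5}
chrom    pos rsid nearest_locus  nearest_distance chromhmm_states fantom5 element_context interacting_genes
 chr1  12501 rsP1          TGT1             19599               .     yes        enhancer              TGT1
 chr1  52501 rsP2          TGT1             17600             Enh      no        enhancer              TGT2
 chr1  92501 rsP3          TGT2             17600               .     yes        enhancer              TGT3
 chr1 132501 rsP4          TGT3             17600             Enh      no        enhancer              TGT4
 chr1 172501 rsP5          TGT4             17600               .     yes        enhancer              TGT5
```

All five planted pass-all variants are recovered; the four planted
near-misses (each engineered to fail exactly one criterion) are
rejected.  The same pipeline is available as a CLI
(`snplink simulate / collapse-peaks / filter-hic / build-regulatory /
run-filter / permute / motif-delta`); every CLI run writes a manifest
with input SHA-256 hashes and the thresholds used.

## Worked example

The package ships a curated table of 36 fine-mapped type 1 diabetes
variants that pass the four-criterion cascade in regulatory T cells
(`snplink.datasets`).  Recomputing the headline numbers from the raw
records:

```python
from snplink.datasets import load_t1d_hits, summarise_hits
summarise_hits(load_t1d_hits())
```

```
{'n_variants': 36, 'n_loci': 14, 'n_multi_variant_loci': 8,
 'largest_locus': 'CD69', 'n_variants_largest_locus': 9,
 'n_unique_interacting_genes': 47, 'n_enhancer_context': 25,
 'n_promoter_context': 10, 'n_both_context': 1,
 'enhancer_pct_of_single_class': 71.4}
```

That is: 36 variants spread over 14 nearest-gene loci, 8 loci carrying
two or more variants, 9 variants at the largest (CD69) locus, 47 unique
genes reached through chromatin contacts, and 71.4% of the
single-class variants sitting in enhancer (rather than promoter)
context — the signature expected of distal regulatory variation.

The `examples/` directory contains one short narrative script per
capability (end-to-end prioritisation, peak collapsing, Hi-C filtering,
worked-example summary, permutation enrichment, motif deltas); each
prints its computed numbers with interpretation:

```bash
python examples/01_end_to_end_prioritisation.py
```

## Layout

```
src/snplink/
  intervals.py    0-based half-open genomic intervals: parse, merge, nearest, index
  atac.py         summit extension and iterative most-significant collapsing
  hic.py          fixed-bin contacts, joint BH adjustment, significance filters
  regulatory.py   TSS promoters, chromHMM class mapping, FANTOM5, merged element sets
  cascade.py      the four-criterion filter, gene linking, report tables
  stats.py        Fisher gene-set overlap, whole-workflow permutation test
  motifs.py       PWMs, allele-specific best-placement log-odds deltas
  fixtures.py     deterministic synthetic bundles with planted ground truth
  datasets.py     packaged worked-example table and its summaries
  cli.py          thin click CLI over the above
```

See `docs/methods.md` for the model, parameter choices and limitations.
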