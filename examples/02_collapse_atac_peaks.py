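"""Collapsing ATAC-seq summits into a non-redundant fixed-width peak set.

Summits from multiple samples often pile up around the same open-chromatin
site.  Each summit is extended to a 500 bp window; overlapping windows are
resolved by keeping the most significant summit and discarding the rest,
iteratively, so the final peak set is non-overlapping.
"""

from snplink.atac import PeakSummit, collapse_summits, extend_summit

# Three samples called summits near the same site, plus one distant site.
summits = [
    PeakSummit("chr1", 10_000, significance=95.0, sample_label="donor1"),
    PeakSummit("chr1", 10_120, significance=60.0, sample_label="donor2"),
    PeakSummit("chr1", 10_310, significance=80.0, sample_label="donor3"),
    PeakSummit("chr1", 40_000, significance=30.0, sample_label="donor1"),
]

print("Input summits (pos, -log10 p, sample):")
for s in summits:
    iv = extend_summit(s).interval
    print(f"  {s.summit_pos:>7,}  {s.significance:5.1f}  {s.sample_label}"
          f"   window [{iv.start:,}, {iv.end:,})")

peaks = collapse_summits(summits)
print(f"\n{len(summits)} summits -> {len(peaks)} non-redundant 500 bp peaks:")
for p in peaks:
    print(f"  {p.interval.chrom}:{p.interval.start:,}-{p.interval.end:,}"
          f"  kept summit at {p.summit.summit_pos:,} ({p.summit.sample_label})")

# The donor2 summit (60.0) overlaps the stronger donor1 window and is
# removed; donor3 (80.0) overlaps donor1's window too and is also removed,
# even though it beats donor2 — survival is decided against *retained*
# peaks in significance order, not pairwise.
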