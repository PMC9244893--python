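"""Allele-specific motif scoring: does a variant change TF binding?

Builds a PWM from counts, scores the best placement covering the variant
for each allele (both strands, all offsets), and reports the log2-odds
delta.  Positive delta means the alternate allele matches the motif
better than the reference.
"""

from snplink.cascade import Variant
from snplink.motifs import PWM, delta_binding

# A 6-bp motif with a strongly preferred A at position 3 (counts per base
# A, C, G, T at each motif position).
counts = [
    [20, 5, 5, 5],
    [5, 20, 5, 5],
    [30, 1, 2, 2],
    [33, 0, 1, 1],   # the critical position
    [5, 5, 20, 5],
    [5, 5, 5, 20],
]
pwm = PWM.from_counts("TOY_MOTIF", counts)

# 21-bp sequence context around the variant; the variant sits at offset 10.
context = "GGGGGGGCAAAAGTGGGGGGG"
offset = 10  # reference base 'A' is at the motif's critical position

for ref, alt in [("A", "C"), ("A", "G")]:
    v = Variant("chr1", 5_000_000, ref=ref, alt=alt, rsid="rsExample")
    d = delta_binding(v, context, offset, pwm)
    direction = "weakens" if d.delta < 0 else "strengthens"
    print(f"{ref}>{alt}: best ref score {d.best_ref_score:6.2f} bits, "
          f"best alt score {d.best_alt_score:6.2f} bits, "
          f"delta {d.delta:+.2f} ({direction} the {d.motif_id} match)")
    o, strand = d.ref_placement
    print(f"       best reference placement: offset {o}, strand {strand}")
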