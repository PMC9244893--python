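"""Seeded generation of a toy genome and every workflow input, with
planted structure, so each stage and the end-to-end cascade can be tested
offline.

The generator writes a complete input bundle (chromosome sizes, FASTA,
gene models, chromHMM segmentation, FANTOM5-style enhancer BED, MACS2
narrowPeak, TF ChIP peak BED, TF footprint BED, Hi-C interaction table,
variant TSV) plus a truth JSON.  Two kinds of variants are planted:

* *pass-all* variants constructed to satisfy all four cascade criteria,
  sitting in an ATAC peak, a TF peak and an enhancer inside an anchor bin
  whose partner bin contains a gene (the expected target);
* *near-miss* variants that fail exactly one named criterion each.

Planted sites live in a reserved stretch of each chromosome and all random
background features are confined to a disjoint stretch, so the truth
labels hold by construction, for every seed.  The interaction noise model
is deliberately simple — power-law distance decay with Poisson counts and
Poisson upper-tail P-values — it exists to exercise the post-caller
filters, not to emulate a real Hi-C background caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.stats

from snplink.hic import GenomicBin, InteractionRecord, pos_to_bin
from snplink.regulatory import CHROMHMM_STATES

NEAR_MISS_KINDS = ("atac", "hic", "regulatory", "tf")

# Roadmap core-model numbering for the 15 states.
_STATE_NUMBERS = {
    "TssA": 1, "TssAFlnk": 2, "TxFlnk": 3, "Tx": 4, "TxWk": 5, "EnhG": 6,
    "Enh": 7, "ZNF/Rpts": 8, "Het": 9, "TssBiv": 10, "BivFlnk": 11,
    "EnhBiv": 12, "ReprPC": 13, "ReprPCWk": 14, "Quies": 15,
}

# Chromosome layout fractions: planted sites in [0, 0.40), background
# features in [0.50, 1.0); the gap keeps 500 bp peaks and 5 kb bins from
# leaking across.
_PLANTED_END = 0.40
_BACKGROUND_START = 0.50


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic bundle."""

    seed: int
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    resolution: int = 5000
    n_genes: int = 30
    n_atac_summits: int = 150
    n_tf_peaks: int = 60
    n_fantom: int = 40
    n_background_interactions: int = 400
    n_variants: int = 60
    n_planted_pass: int = 5
    n_planted_near_miss: int = 4
    decay_exponent: float = 1.0
    amplitude: float = 20.0
    planted_inflation: float = 10.0

    def __post_init__(self) -> None:
        if self.n_planted_pass + self.n_planted_near_miss > self.n_variants:
            raise ValueError("planted counts exceed n_variants")
        if min(self.n_planted_pass, self.n_planted_near_miss, self.n_variants) < 0:
            raise ValueError("counts must be non-negative")
        n_slots = self.n_planted_pass + self.n_planted_near_miss
        # each planted site needs an anchor slot + partner slot, 4 bins apart
        needed = (n_slots * 8 + 4) * self.resolution
        if needed > int(self.chrom_length * _PLANTED_END) * self.n_chroms:
            raise ValueError(
                f"chromosomes too short for {n_slots} planted sites at "
                f"resolution {self.resolution}"
            )
        if self.chrom_length < 4 * self.resolution:
            raise ValueError("chromosome shorter than four bins")


FILES = {
    "genome_sizes": "genome.sizes",
    "fasta": "genome.fa",
    "genes": "genes.tsv",
    "chromhmm": "chromhmm.bed",
    "fantom": "fantom_enhancers.bed",
    "narrowpeak": "atac_summits.narrowPeak",
    "tf_peaks": "tf_peaks.bed",
    "footprints": "footprints.bed",
    "interactions": "interactions.tsv",
    "variants": "variants.tsv",
    "truth": "truth.json",
}


@dataclass
class FixtureBundle:
    """Paths of one generated bundle plus its truth labels."""

    directory: Path
    spec: FixtureSpec
    truth: dict = field(default_factory=dict)

    def path(self, key: str) -> Path:
        return self.directory / FILES[key]


def interaction_noise_model(
    bins: list[GenomicBin],
    decay_exponent: float = 1.0,
    depth: int = 400,
    seed: int = 0,
    planted: list[tuple[GenomicBin, GenomicBin, float]] = (),
    amplitude: float = 20.0,
) -> list[InteractionRecord]:
    """Sample an interaction table with power-law distance decay.

    ``depth`` random intra-chromosomal bin pairs are drawn from ``bins``;
    each pair at separation ``s`` bins has expected count
    ``amplitude * s**-decay_exponent``, the observed count is Poisson, and
    the P-value is the Poisson upper tail of the observed count under that
    expectation — so background pairs are calibrated (conservative, as the
    counts are discrete) and ``planted`` pairs, whose counts are drawn with
    expectation inflated ``k``-fold (floored at 30 reads), come out highly
    significant.
    """
    if decay_exponent <= 0:
        raise ValueError("decay_exponent must be positive")
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[GenomicBin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    chroms = sorted(c for c in by_chrom if len(by_chrom[c]) >= 2)
    records: list[InteractionRecord] = []
    seen: set[tuple] = set()
    planted_keys = {
        (a.chrom, min(a.index, b.index), max(a.index, b.index)) for a, b, _ in planted
    }

    def sample(mu_obs: float, mu_null: float, bin_a: GenomicBin, bin_b: GenomicBin) -> None:
        count = int(rng.poisson(mu_obs))
        p = float(scipy.stats.poisson.sf(count - 1, mu_null))
        records.append(InteractionRecord(bin_a, bin_b, count, min(p, 1.0)))

    for bin_a, bin_b, inflation in planted:
        sep = abs(bin_a.index - bin_b.index)
        mu_null = amplitude * sep ** -decay_exponent
        sample(max(inflation * mu_null, 30.0), mu_null, bin_a, bin_b)
        seen.add((bin_a.chrom, min(bin_a.index, bin_b.index), max(bin_a.index, bin_b.index)))
    if chroms and depth > 0:
        for _ in range(depth):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pool = by_chrom[chrom]
            i, j = rng.choice(len(pool), size=2, replace=False)
            a, b = pool[int(i)], pool[int(j)]
            if a.index == b.index:
                continue
            key = (chrom, min(a.index, b.index), max(a.index, b.index))
            if key in seen or key in planted_keys:
                continue
            seen.add(key)
            sep = abs(a.index - b.index)
            mu = amplitude * sep ** -decay_exponent
            sample(mu, mu, a, b)
    return records


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def generate(spec: FixtureSpec, directory) -> FixtureBundle:
    """Write a complete, bit-reproducible input bundle under ``directory``."""
    rng = np.random.default_rng(spec.seed)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    res = spec.resolution
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    L = spec.chrom_length
    planted_end = int(L * _PLANTED_END)
    bg_start = int(L * _BACKGROUND_START)

    # ---- genome ---------------------------------------------------------
    sequences = {c: _random_sequence(rng, L) for c in chroms}
    with open(directory / FILES["genome_sizes"], "wt") as fh:
        for c in chroms:
            fh.write(f"{c}\t{L}\n")
    with open(directory / FILES["fasta"], "wt") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            seq = sequences[c]
            for i in range(0, L, 80):
                fh.write(seq[i:i + 80] + "\n")

    # ---- planted site layout -------------------------------------------
    # Anchor slots at odd multiples of 8 bins, partner 4 bins further.
    n_slots = spec.n_planted_pass + spec.n_planted_near_miss
    slots = []  # (chrom, anchor_bin_index, partner_bin_index)
    per_chrom = max(1, -(-n_slots // spec.n_chroms))
    s = 0
    for c in chroms:
        for k in range(per_chrom):
            if s >= n_slots:
                break
            anchor = 2 + k * 8
            partner = anchor + 4
            if (partner + 1) * res > planted_end:
                raise ValueError("planted zone too small for requested slots")
            slots.append((c, anchor, partner))
            s += 1

    kinds = (["pass"] * spec.n_planted_pass
             + [NEAR_MISS_KINDS[i % len(NEAR_MISS_KINDS)] for i in range(spec.n_planted_near_miss)])

    genes: list[tuple[str, int, int, str, str]] = []
    fantom: list[tuple[str, int, int]] = []
    chromhmm: list[tuple[str, int, int, str]] = []
    summits: list[tuple[str, int, float, str]] = []
    tf_peaks: list[tuple[str, int, int]] = []
    footprints: list[tuple[str, int, int]] = []
    planted_contacts: list[tuple[GenomicBin, GenomicBin, float]] = []
    variants: list[dict] = []
    truth: dict = {"seed": spec.seed, "planted_pass": [], "near_miss": []}

    for idx, ((chrom, anchor, partner), kind) in enumerate(zip(slots, kinds)):
        pos = anchor * res + res // 2  # 0-based variant position, mid-bin
        rsid = f"rsP{idx + 1}" if kind == "pass" else f"rsM{idx + 1}"
        gene_name = f"TGT{idx + 1}"
        # partner-bin gene: body well inside the bin so its 2 kb promoter
        # window stays inside the bin too
        gstart = partner * res + 2100
        gend = partner * res + res - 100
        genes.append((chrom, gstart, gend, "+", gene_name))
        if kind != "atac":
            summits.append((chrom, pos, 80.0 + idx, "planted"))
        if kind != "tf":
            tf_peaks.append((chrom, pos - 150, pos + 150))
            footprints.append((chrom, pos - 20, pos + 20))
        if kind != "regulatory":
            # alternate enhancer provenance between FANTOM5 and chromHMM
            if idx % 2 == 0:
                fantom.append((chrom, pos - 200, pos + 200))
            else:
                chromhmm.append((chrom, pos - 200, pos + 200, "7_Enh"))
        if kind != "hic":
            planted_contacts.append(
                (GenomicBin(chrom, anchor, res), GenomicBin(chrom, partner, res),
                 spec.planted_inflation)
            )
        ref = sequences[chrom][pos]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        variants.append({"chrom": chrom, "pos": pos, "rsid": rsid, "ref": ref, "alt": alt})
        entry = {"rsid": rsid, "chrom": chrom, "pos_1based": pos + 1}
        if kind == "pass":
            entry["expected_genes"] = [gene_name]
            truth["planted_pass"].append(entry)
        else:
            entry["fails"] = kind
            truth["near_miss"].append(entry)

    # ---- background features (confined to the background zone) ---------
    def bg_positions(n: int, margin: int) -> np.ndarray:
        return rng.integers(bg_start + margin, L - margin, size=n)

    for p in sorted(bg_positions(max(spec.n_genes - len(slots), 0), 12000)):
        strand = "+" if rng.random() < 0.5 else "-"
        width = int(rng.integers(2000, 10000))
        genes.append((chroms[int(rng.integers(spec.n_chroms))], int(p), int(p) + width,
                      strand, f"BG{p}"))
    for p in sorted(bg_positions(spec.n_fantom, 1000)):
        c = chroms[int(rng.integers(spec.n_chroms))]
        fantom.append((c, int(p), int(p) + int(rng.integers(200, 800))))
    # chromHMM tiling of the background zone, 2 kb blocks, Quies-weighted,
    # with the standard numeric state prefixes
    state_pool = sorted(CHROMHMM_STATES)
    weights = np.array([3.0 if s == "Quies" else 1.0 for s in state_pool])
    weights /= weights.sum()
    for c in chroms:
        for block_start in range(bg_start, L - 2000, 20000):
            state = str(rng.choice(state_pool, p=weights))
            chromhmm.append((c, block_start, block_start + 2000,
                             f"{_STATE_NUMBERS[state]}_{state}"))
    for p in bg_positions(max(spec.n_atac_summits - len(slots), 0), 600):
        c = chroms[int(rng.integers(spec.n_chroms))]
        summits.append((c, int(p), float(rng.uniform(2, 40)), f"bg_{int(rng.integers(2))}"))
    for p in bg_positions(spec.n_tf_peaks, 2000):
        c = chroms[int(rng.integers(spec.n_chroms))]
        width = int(rng.integers(300, 1500))
        tf_peaks.append((c, int(p), int(p) + width))
        footprints.append((c, int(p) + width // 2 - 15, int(p) + width // 2 + 15))
    n_bg_variants = spec.n_variants - len(variants)
    for p in bg_positions(n_bg_variants, 10):
        c = chroms[int(rng.integers(spec.n_chroms))]
        ref = sequences[c][int(p)]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        variants.append({"chrom": c, "pos": int(p), "rsid": f"rsB{int(p)}",
                         "ref": ref, "alt": alt})

    # ---- interactions ---------------------------------------------------
    bg_bins = [GenomicBin(c, i, res)
               for c in chroms
               for i in range(bg_start // res, L // res)]
    records = interaction_noise_model(
        bg_bins,
        decay_exponent=spec.decay_exponent,
        depth=spec.n_background_interactions,
        seed=spec.seed + 1,
        planted=planted_contacts,
        amplitude=spec.amplitude,
    )

    # ---- write everything, deterministically sorted ---------------------
    genes.sort()
    with open(directory / FILES["genes"], "wt") as fh:
        fh.write("# chrom\tstart\tend\tstrand\tname\n")
        for row in genes:
            fh.write("\t".join(map(str, row)) + "\n")
    fantom.sort()
    with open(directory / FILES["fantom"], "wt") as fh:
        for c, a, b in fantom:
            fh.write(f"{c}\t{a}\t{b}\n")
    chromhmm.sort()
    with open(directory / FILES["chromhmm"], "wt") as fh:
        for c, a, b, state in chromhmm:
            fh.write(f"{c}\t{a}\t{b}\t{state}\n")
    summits.sort()
    with open(directory / FILES["narrowpeak"], "wt") as fh:
        for c, pos, sig, label in summits:
            start, end = pos - 250, pos + 250
            fh.write(f"{c}\t{start}\t{end}\t{label}\t0\t.\t0\t{sig:.4f}\t-1\t250\n")
    tf_peaks.sort()
    with open(directory / FILES["tf_peaks"], "wt") as fh:
        for c, a, b in tf_peaks:
            fh.write(f"{c}\t{a}\t{b}\n")
    footprints.sort()
    with open(directory / FILES["footprints"], "wt") as fh:
        for c, a, b in footprints:
            fh.write(f"{c}\t{a}\t{b}\n")
    records.sort(key=lambda r: (r.bin_a.chrom, r.bin_a.index, r.bin_b.index))
    from snplink.hic import write_interactions

    with open(directory / FILES["interactions"], "wt") as fh:
        write_interactions(records, fh)
    variants.sort(key=lambda v: (v["chrom"], v["pos"]))
    with open(directory / FILES["variants"], "wt") as fh:
        fh.write("# chrom\tpos_1based\trsid\talleles\n")
        for v in variants:
            fh.write(f"{v['chrom']}\t{v['pos'] + 1}\t{v['rsid']}\t{v['ref']}/{v['alt']}\n")
    with open(directory / FILES["truth"], "wt") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return FixtureBundle(directory, spec, truth)


def load_bundle(directory):
    """Parse a generated bundle back into workflow-ready objects.

    Returns a dict with keys: variants, summits, collapsed_peaks (list of
    intervals), interactions (post-caller filtered), regulatory
    (RegulatorySet), tf_peaks, footprints, genes, genome.
    """
    from snplink.atac import collapse_summits, read_narrowpeak
    from snplink.cascade import read_variants_tsv
    from snplink.hic import filter_interactions, read_interactions
    from snplink.intervals import read_bed, read_genome_table
    from snplink.regulatory import build_regulatory_set, read_genes

    directory = Path(directory)
    summits = read_narrowpeak(directory / FILES["narrowpeak"])
    collapsed = collapse_summits(summits)
    interactions_raw = read_interactions(directory / FILES["interactions"])
    kept, summary = filter_interactions(interactions_raw)
    genes = read_genes(directory / FILES["genes"])
    regulatory = build_regulatory_set(
        fantom=read_bed(directory / FILES["fantom"]),
        chromhmm_segments=read_bed(directory / FILES["chromhmm"]),
        genes=genes,
    )
    return {
        "variants": read_variants_tsv(directory / FILES["variants"]),
        "summits": summits,
        "collapsed_peaks": [p.interval for p in collapsed],
        "interactions_raw": interactions_raw,
        "interactions": kept,
        "filter_summary": summary,
        "regulatory": regulatory,
        "tf_peaks": read_bed(directory / FILES["tf_peaks"]),
        "footprints": read_bed(directory / FILES["footprints"]),
        "genes": genes,
        "genome": read_genome_table(directory / FILES["genome_sizes"]),
    }
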