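"""Packaged worked-example data and summary statistics over it.

The shipped table (``data/t1d_treg_hits.tsv``) lists 36 fine-mapped type 1
diabetes variants that survive the four-criterion regulatory T cell
cascade, with nearest gene, chromHMM state, FANTOM5 enhancer support and
3D-interacting genes.  :func:`summarise_hits` recomputes the headline
counts of that worked example (variant total, locus grouping, target-gene
tally, enhancer-vs-promoter split) from the records.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from snplink.cascade import context_from_labels

# One curated symbol is spelled two ways across records; normalisation is
# applied only when the caller asks for it.
GENE_SYNONYMS = {"RMB17": "RBM17"}

_HITS_FILE = "t1d_treg_hits.tsv"


def load_t1d_hits(normalise_symbols: bool = False) -> pd.DataFrame:
    """Load the worked-example variant table.

    Columns: chrom, pos (1-based), rsid, nearest_locus, chromhmm_state
    (``None`` when absent), fantom5 (bool), interacting_genes (list of
    symbols, possibly empty).  ``normalise_symbols=True`` maps known
    spelling variants onto one symbol.
    """
    with resources.files("snplink").joinpath("data", _HITS_FILE).open("rt") as handle:
        df = pd.read_csv(handle, sep="\t", comment="#", dtype={"pos": int})
    df["chromhmm_state"] = df["chromhmm_state"].where(df["chromhmm_state"] != ".", None)
    df["fantom5"] = df["fantom5"].map({"yes": True, "no": False})

    def genes(cell: str) -> list[str]:
        if cell == "." or not cell:
            return []
        symbols = [g.strip() for g in cell.split(",") if g.strip()]
        if normalise_symbols:
            symbols = [GENE_SYNONYMS.get(g, g) for g in symbols]
        return symbols

    df["interacting_genes"] = df["interacting_genes"].map(genes)
    return df


def summarise_hits(df: pd.DataFrame) -> dict:
    """Recompute the worked example's headline counts from the records.

    Returns: total variants; number of distinct nearest-gene loci; loci
    with multiple (>= 2) variants; variants at the largest locus (CD69);
    unique 3D-interacting genes after synonym normalisation; and the
    enhancer-context split (variants classed as enhancer / promoter /
    both, with the enhancer percentage taken over the unambiguous
    single-class variants).
    """
    contexts = [
        context_from_labels(state, bool(f5))
        for state, f5 in zip(df["chromhmm_state"], df["fantom5"])
    ]
    n_enh = sum(c == "enhancer" for c in contexts)
    n_prom = sum(c == "promoter" for c in contexts)
    n_both = sum(c == "both" for c in contexts)
    n_single = n_enh + n_prom
    locus_sizes = df.groupby("nearest_locus").size()
    genes = {
        GENE_SYNONYMS.get(g, g)
        for cell in df["interacting_genes"]
        for g in cell
    }
    return {
        "n_variants": int(len(df)),
        "n_loci": int(locus_sizes.size),
        "n_multi_variant_loci": int((locus_sizes >= 2).sum()),
        "largest_locus": str(locus_sizes.idxmax()),
        "n_variants_largest_locus": int(locus_sizes.max()),
        "n_unique_interacting_genes": int(len(genes)),
        "n_enhancer_context": int(n_enh),
        "n_promoter_context": int(n_prom),
        "n_both_context": int(n_both),
        "enhancer_pct_of_single_class": round(100.0 * n_enh / n_single, 1) if n_single else 0.0,
    }
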