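"""Significance testing for the cascade's output: Fisher's exact test on
2x2 tables, gene-set overlap enrichment (TF-bound x disease genes), and a
seeded permutation test of the whole filtering workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.stats

from snplink.cascade import CascadeResult, Variant, gene_region_index
from snplink.intervals import GenomicInterval, IntervalIndex
from snplink.regulatory import GeneModel

ALTERNATIVES = {"greater", "less", "two_sided"}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = in-set / out-of-set, columns =
    condition / background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact(table: ContingencyTable2x2, alternative: str = "greater") -> float:
    """Exact hypergeometric P-value for a 2x2 table.

    ``greater`` tests for enrichment of the top-left cell given the
    margins; ``two_sided`` sums all tables at most as probable as the
    observed one.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(ALTERNATIVES)}")
    scipy_alt = "two-sided" if alternative == "two_sided" else alternative
    return float(scipy.stats.fisher_exact(table.as_array(), alternative=scipy_alt)[1])


def gene_overlap_enrichment(
    disease_genes: set[str] | Sequence[str],
    tf_bound_genes: set[str] | Sequence[str],
    universe_genes: set[str] | Sequence[str],
    alternative: str = "greater",
) -> tuple[ContingencyTable2x2, float]:
    """Enrichment of TF-bound genes within a disease gene set.

    Both input sets must be subsets of the universe; the 2x2 table
    cross-tabulates disease membership (rows) against TF binding (columns).
    """
    disease, tf, universe = set(disease_genes), set(tf_bound_genes), set(universe_genes)
    for label, subset in (("disease", disease), ("TF-bound", tf)):
        extra = subset - universe
        if extra:
            raise ValueError(f"{label} genes outside the universe: {sorted(extra)[:10]}")
    a = len(disease & tf)
    b = len(disease - tf)
    c = len(tf - disease)
    d = len(universe - disease - tf)
    table = ContingencyTable2x2(a, b, c, d)
    return table, fisher_exact(table, alternative=alternative)


def tf_bound_genes(genes: Sequence[GeneModel], tf_peaks: Sequence[GenomicInterval],
                   promoter_upstream: int = 2000) -> set[str]:
    """Genes whose body or promoter window overlaps a TF peak — the same
    rule used for variant-to-gene linking."""
    index = gene_region_index(genes, promoter_upstream=promoter_upstream)
    return {hit.name for peak in tf_peaks for hit in index.overlapping(peak) if hit.name}


@dataclass
class PermutationReport:
    """Outcome of the seeded workflow permutation test."""

    n_perm: int
    seed: int
    observed_pass_count: int
    n_observed: int
    per_perm_pass_counts: list[int] = field(default_factory=list)
    per_perm_p_values: list[float] = field(default_factory=list)
    background: str = "user-supplied pool"

    @property
    def mean_p(self) -> float:
        return float(np.mean(self.per_perm_p_values))

    @property
    def empirical_rank_p(self) -> float:
        """(1 + #{perm pass count >= observed}) / (n_perm + 1): the cleaner
        summary reported alongside the per-permutation Fisher mean."""
        ge = sum(c >= self.observed_pass_count for c in self.per_perm_pass_counts)
        return (1 + ge) / (self.n_perm + 1)

    def as_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "seed": self.seed,
            "background": self.background,
            "n_observed": self.n_observed,
            "observed_pass_count": self.observed_pass_count,
            "per_perm_pass_counts": self.per_perm_pass_counts,
            "per_perm_p_values": self.per_perm_p_values,
            "mean_p": self.mean_p,
            "empirical_rank_p": self.empirical_rank_p,
        }


def permutation_workflow_test(
    observed_variants: Sequence[Variant],
    background_pool: Sequence[Variant],
    cascade_fn: Callable[[Sequence[Variant]], Sequence[CascadeResult]],
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationReport:
    """Is the observed pass count higher than for random variant draws?

    Each permutation draws ``len(observed_variants)`` variants from the
    pool without replacement (seeded, independent across permutations) and
    runs the cascade on them.  The per-permutation P-value is Fisher
    "greater" on ``[[obs_pass, obs_fail], [perm_pass, perm_fail]]``; the
    report carries the mean of those P-values and an empirical rank P.

    ``cascade_fn`` maps a variant list to cascade results with every other
    workflow input fixed (see :func:`snplink.cascade.run_cascade`).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    n_obs = len(observed_variants)
    if len(background_pool) < n_obs:
        raise ValueError(
            f"background pool ({len(background_pool)}) smaller than observed set ({n_obs})"
        )
    observed_results = cascade_fn(observed_variants)
    obs_pass = sum(r.passes for r in observed_results)
    report = PermutationReport(
        n_perm=n_perm, seed=seed, observed_pass_count=obs_pass, n_observed=n_obs
    )
    rng = np.random.default_rng(seed)
    pool = list(background_pool)
    for _ in range(n_perm):
        picks = rng.choice(len(pool), size=n_obs, replace=False)
        perm_results = cascade_fn([pool[i] for i in picks])
        perm_pass = sum(r.passes for r in perm_results)
        table = ContingencyTable2x2(obs_pass, n_obs - obs_pass, perm_pass, n_obs - perm_pass)
        report.per_perm_pass_counts.append(perm_pass)
        report.per_perm_p_values.append(fisher_exact(table, alternative="greater"))
    return report
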