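"""The four-criterion cascade, context classification and gene linking."""

import io
import itertools

import numpy as np
import pytest

from snplink.cascade import (
    CascadeResult,
    Variant,
    annotate_nearest,
    attrition_summary,
    classify_element_context,
    context_from_labels,
    link_target_genes,
    read_variants_tsv,
    run_cascade,
    tabulate,
)
from snplink.hic import InteractionRecord, pos_to_bin
from snplink.intervals import GenomicInterval, NoNeighbourError, gap
from snplink.regulatory import GeneModel, build_regulatory_set


def gene(chrom, start, end, strand, name):
    return GeneModel(GenomicInterval(chrom, start, end, strand=strand, name=name), name)


def hic_record(chrom, start_a, start_b, res=5000):
    return InteractionRecord(pos_to_bin(chrom, start_a, res),
                             pos_to_bin(chrom, start_b, res), 10, 1e-4, adj_p=1e-3)


class TestVariantParsing:
    def test_tsv_positions_converted_to_zero_based(self):
        (v,) = read_variants_tsv(io.StringIO("chr1\t1000\trs1\tA/G\n"))
        assert v.pos == 999 and v.display_pos == 1000 and (v.ref, v.alt) == ("A", "G")

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            Variant("c", 10, ref="A", alt="A")

    def test_maf_column_optional(self):
        (v,) = read_variants_tsv(io.StringIO("chr1\t5\trs2\tC/T\t0.23\n"))
        assert v.maf == 0.23


class TestElementContext:
    def test_enhancer_only(self):
        reg = build_regulatory_set(
            chromhmm_segments=[GenomicInterval("c", 0, 100, name="7_Enh")])
        assert classify_element_context(Variant("c", 50, ref="A", alt="G"), reg) == "enhancer"

    def test_promoter_state_plus_fantom_is_both(self):
        # the mixed TssAFlnk + FANTOM5 enhancer situation
        reg = build_regulatory_set(
            fantom=[GenomicInterval("c", 0, 100)],
            chromhmm_segments=[GenomicInterval("c", 0, 100, name="2_TssAFlnk")])
        assert classify_element_context(Variant("c", 50, ref="A", alt="G"), reg) == "both"

    def test_outside_everything_is_none(self):
        reg = build_regulatory_set(chromhmm_segments=[GenomicInterval("c", 0, 10, name="7_Enh")])
        assert classify_element_context(Variant("c", 500, ref="A", alt="G"), reg) == "none"

    @pytest.mark.parametrize("state,fantom,expected", [
        ("Enh", False, "enhancer"),
        ("TssAFlnk", False, "promoter"),
        ("TssAFlnk", True, "both"),
        (None, True, "enhancer"),
        (None, False, "none"),
        ("7_Enh", True, "enhancer"),
    ])
    def test_label_level_classifier(self, state, fantom, expected):
        assert context_from_labels(state, fantom) == expected


class TestGeneLinking:
    def test_partner_bin_gene_listed_once(self):
        # gene spans two distinct partner bins; it must be listed once
        genes = [gene("c", 51_000, 57_000, "+", "G1")]
        records = [hic_record("c", 10_000, 50_000), hic_record("c", 10_000, 56_000)]
        r = CascadeResult(Variant("c", 11_000, ref="A", alt="G"), in_hic_anchor=True)
        link_target_genes(r, records, genes)
        assert r.interacting_genes == ["G1"]
        assert len(r.interacting_regions) == 2

    def test_promoter_overlap_suffices(self):
        # gene body outside the partner bin, promoter window inside it
        genes = [gene("c", 55_000, 60_000, "+", "G2")]
        records = [hic_record("c", 10_000, 50_000)]
        r = CascadeResult(Variant("c", 11_000, ref="A", alt="G"), in_hic_anchor=True)
        link_target_genes(r, records, genes)
        assert r.interacting_genes == ["G2"]

    def test_not_in_anchor_returns_empty(self):
        r = CascadeResult(Variant("c", 0, ref="A", alt="G"), in_hic_anchor=False)
        link_target_genes(r, [hic_record("c", 10_000, 50_000)],
                          [gene("c", 50_000, 55_000, "+", "G")])
        assert r.interacting_genes == [] and r.interacting_regions == []

    def test_random_layouts_match_double_loop_oracle(self):
        rng = np.random.default_rng(40)
        for _ in range(20):
            genes = [gene("chr1", int(s), int(s) + int(rng.integers(1000, 8000)), "+", f"g{i}")
                     for i, s in enumerate(rng.integers(2000, 400_000, 15))]
            records = [hic_record("chr1", int(rng.integers(0, 80)) * 5000,
                                  int(rng.integers(0, 80)) * 5000)
                       for _ in range(20)]
            records = [r for r in records if r.bin_a != r.bin_b]
            vpos = int(rng.integers(0, 400_000))
            r = CascadeResult(Variant("chr1", vpos, ref="A", alt="G"), in_hic_anchor=True)
            link_target_genes(r, records, genes)
            expected = set()
            from snplink.hic import partners_of
            from snplink.regulatory import promoters_from_tss

            for b in partners_of(r.variant.interval, records):
                for g in genes:
                    regions = [g.interval] + [p.interval for p in promoters_from_tss([g])]
                    if any(iv.chrom == b.chrom and iv.start < b.end and b.start < iv.end
                           for iv in regions):
                        expected.add(g.gene_name)
            assert r.interacting_genes == sorted(expected)


class TestNearest:
    def test_upstream_gap(self):
        g = gene("c", 10_000, 20_000, "+", "G")
        name, dist = annotate_nearest(Variant("c", 5000, ref="A", alt="G"), [g])
        assert name == "G" and dist == 4999

    def test_inside_body_distance_zero(self):
        g = gene("c", 10_000, 20_000, "+", "G")
        assert annotate_nearest(Variant("c", 15_000, ref="A", alt="G"), [g]) == ("G", 0)

    def test_no_gene_on_chromosome_raises(self):
        with pytest.raises(NoNeighbourError):
            annotate_nearest(Variant("chrX", 0, ref="A", alt="G"),
                             [gene("chr1", 0, 10, "+", "G")])

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(41)
        genes = [gene("chr1", int(s), int(s) + int(rng.integers(500, 5000)), "+", f"g{i}")
                 for i, s in enumerate(rng.integers(0, 100_000, 25))]
        for _ in range(50):
            v = Variant("chr1", int(rng.integers(0, 100_000)), ref="A", alt="G")
            name, dist = annotate_nearest(v, genes)
            best = min(gap(v.interval, g.interval) for g in genes)
            assert dist == best
            assert name in {g.gene_name for g in genes if gap(v.interval, g.interval) == best}


class TestCascadeProperties:
    def test_planted_variant_passes_and_near_misses_fail_their_criterion(
            self, bundle, cascade_results):
        by_rsid = {r.variant.rsid: r for r in cascade_results}
        for entry in bundle.truth["planted_pass"]:
            r = by_rsid[entry["rsid"]]
            assert r.passes
            assert r.interacting_genes == entry["expected_genes"]
        flag_names = {"atac": "in_atac", "hic": "in_hic_anchor",
                      "regulatory": "in_regulatory", "tf": "in_tf_peak"}
        for entry in bundle.truth["near_miss"]:
            r = by_rsid[entry["rsid"]]
            assert not r.passes
            flags = {k: getattr(r, attr) for k, attr in flag_names.items()}
            assert not flags[entry["fails"]]
            assert sum(flags.values()) == 3

    def test_empty_variant_list_gives_empty_result(self, bundle_data):
        assert run_cascade([], bundle_data["collapsed_peaks"], bundle_data["interactions"],
                           bundle_data["regulatory"], bundle_data["tf_peaks"]) == []

    def test_empty_filter_input_warns_and_fails_that_flag(self, bundle_data, caplog):
        with caplog.at_level("WARNING", logger="snplink.cascade"):
            results = run_cascade(bundle_data["variants"], [], bundle_data["interactions"],
                                  bundle_data["regulatory"], bundle_data["tf_peaks"])
        assert "empty filter input" in caplog.text
        assert not any(r.in_atac for r in results)
        assert not any(r.passes for r in results)

    def test_pass_set_equals_intersection_of_single_criterion_filters(self, bundle_data):
        """Applying the four single-criterion filters independently and
        intersecting gives exactly run_cascade's passing set."""
        full = run_cascade(bundle_data["variants"], bundle_data["collapsed_peaks"],
                           bundle_data["interactions"], bundle_data["regulatory"],
                           bundle_data["tf_peaks"], link_genes=False)
        sets = []
        for flag in ("in_atac", "in_hic_anchor", "in_regulatory", "in_tf_peak"):
            sets.append({r.variant for r in full if getattr(r, flag)})
        intersection = set.intersection(*sets)
        assert {r.variant for r in full if r.passes} == intersection

    def test_monotone_in_filter_inputs(self, bundle_data):
        """Adding intervals to a filter input can only grow the passing set."""
        base = run_cascade(bundle_data["variants"], bundle_data["collapsed_peaks"][:3],
                           bundle_data["interactions"], bundle_data["regulatory"],
                           bundle_data["tf_peaks"], link_genes=False)
        grown = run_cascade(bundle_data["variants"], bundle_data["collapsed_peaks"],
                            bundle_data["interactions"], bundle_data["regulatory"],
                            bundle_data["tf_peaks"], link_genes=False)
        base_pass = {r.variant for r in base if r.passes}
        grown_pass = {r.variant for r in grown if r.passes}
        assert base_pass <= grown_pass

    def test_interacting_genes_have_an_audit_trail(self, bundle_data, cascade_results):
        """Every linked gene of a passing variant is reachable through at
        least one filtered interaction record."""
        from snplink.hic import partners_of
        from snplink.cascade import gene_region_index

        index = gene_region_index(bundle_data["genes"])
        for r in cascade_results:
            if not r.passes:
                continue
            reachable = set()
            for b in partners_of(r.variant.interval, bundle_data["interactions"]):
                reachable.update(h.name for h in index.overlapping(b.interval))
            assert set(r.interacting_genes) <= reachable

    def test_result_order_deterministic(self, bundle_data):
        a = run_cascade(bundle_data["variants"], bundle_data["collapsed_peaks"],
                        bundle_data["interactions"], bundle_data["regulatory"],
                        bundle_data["tf_peaks"], link_genes=False)
        shuffled = list(bundle_data["variants"])[::-1]
        b = run_cascade(shuffled, bundle_data["collapsed_peaks"],
                        bundle_data["interactions"], bundle_data["regulatory"],
                        bundle_data["tf_peaks"], link_genes=False)
        assert [r.variant for r in a] == [r.variant for r in b]


class TestReport:
    def test_zero_passing_variants_gives_header_only(self):
        df = tabulate([])
        assert len(df) == 0 and "rsid" in df.columns

    def test_rows_in_coordinate_order_with_display_coordinates(self, cascade_results):
        df = tabulate(cascade_results)
        n_pass = sum(r.passes for r in cascade_results)
        assert len(df) == n_pass
        assert list(df["pos"]) == sorted(df["pos"].tolist()) or df["chrom"].nunique() > 1
        by_rsid = {r.variant.rsid: r for r in cascade_results}
        for _, row in df.iterrows():
            assert row["pos"] == by_rsid[row["rsid"]].variant.display_pos

    def test_attrition_summary_counts(self, cascade_results):
        summary = attrition_summary(cascade_results)
        assert summary["n_input"] == len(cascade_results)
        assert summary["n_pass"] == sum(r.passes for r in cascade_results)
        assert summary["n_pass"] <= min(summary["n_in_atac"], summary["n_in_hic_anchor"],
                                        summary["n_in_regulatory"], summary["n_in_tf_peak"])
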