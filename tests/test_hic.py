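"""Binning, BH adjustment and the post-caller interaction filters."""

import io

import numpy as np
import pytest

from snplink.hic import (
    GenomicBin,
    InteractionRecord,
    bh_adjust,
    filter_interactions,
    partners_of,
    pos_to_bin,
    read_interactions,
    write_interactions,
)
from snplink.intervals import GenomicInterval


def record(chrom_a, start_a, chrom_b, start_b, count, p, res=5000):
    return InteractionRecord(
        pos_to_bin(chrom_a, start_a, res), pos_to_bin(chrom_b, start_b, res), count, p
    )


class TestBinning:
    @pytest.mark.parametrize(
        "pos,expected", [(0, 0), (4999, 0), (5000, 1), (123_456, 24)]
    )
    def test_floor_division(self, pos, expected):
        assert pos_to_bin("c", pos, 5000).index == expected

    def test_negative_position_rejected(self):
        with pytest.raises(ValueError):
            pos_to_bin("c", -1, 5000)

    def test_random_positions_match_integer_division(self):
        rng = np.random.default_rng(20)
        for pos in rng.integers(0, 10**8, size=500):
            for res in (5000, 20000):
                assert pos_to_bin("c", int(pos), res).index == int(pos) // res

    def test_record_canonical_orientation(self):
        r = record("c", 50_000, "c", 10_000, 5, 0.01)
        assert r.bin_a.index <= r.bin_b.index


def bh_oracle(p):
    """Textbook step-up: adj(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        adj_sorted[rank] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBH:
    def test_hand_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_step_up_formula_on_random_vectors(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 200)))
            assert np.max(np.abs(bh_adjust(p) - bh_oracle(p))) < 1e-12

    def test_adjusted_at_least_raw_and_rank_preserving(self):
        rng = np.random.default_rng(22)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestFilter:
    def test_adjacent_bins_excluded_by_strict_distance(self):
        # start distance exactly 5000 is not > 5000
        r = record("c", 10_000, "c", 15_000, 10, 1e-6)
        kept, summary = filter_interactions([r])
        assert kept == [] and summary.n_fail_distance == 1

    def test_boundary_thresholds_kept(self):
        # count 5 and adj_p 0.049 both sit on the keep side
        r = record("c", 10_000, "c", 25_000, 5, 0.049)
        kept, _ = filter_interactions([r])
        assert len(kept) == 1 and kept[0].adj_p == pytest.approx(0.049)

    def test_inter_chromosomal_dropped_not_errored(self):
        r = record("chr1", 0, "chr2", 0, 50, 1e-9)
        kept, summary = filter_interactions([r])
        assert kept == [] and summary.n_inter_chromosomal == 1

    def test_mixed_resolutions_rejected(self):
        a = record("c", 0, "c", 50_000, 5, 0.01)
        b = record("c", 0, "c", 50_000, 5, 0.01, res=20_000)
        with pytest.raises(ValueError, match="resolution"):
            filter_interactions([a, b])

    def test_matches_row_wise_predicate_oracle(self):
        rng = np.random.default_rng(23)
        records = [
            record("chr1", int(rng.integers(0, 200)) * 5000,
                   "chr1", int(rng.integers(0, 200)) * 5000,
                   int(rng.integers(0, 20)), float(rng.uniform()))
            for _ in range(2000)
        ]
        records = [r for r in records if r.bin_a != r.bin_b]
        kept, _ = filter_interactions(records)
        adj = bh_oracle([r.p_value for r in records])
        expected = {
            (r.bin_a, r.bin_b)
            for r, a in zip(records, adj)
            if a < 0.05 and r.read_count >= 5 and r.bin_distance > 5000
        }
        assert {(r.bin_a, r.bin_b) for r in kept} == expected

    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(24)
        records = [
            record("chr1", int(rng.integers(0, 100)) * 5000,
                   "chr1", int(rng.integers(0, 100)) * 5000,
                   int(rng.integers(0, 30)), float(rng.uniform(0, 0.2)))
            for _ in range(300)
        ]
        records = [r for r in records if r.bin_a != r.bin_b]
        kept, _ = filter_interactions(records)
        keys = {(r.bin_a, r.bin_b) for r in kept}
        assert keys <= {(r.bin_a, r.bin_b) for r in records}
        again, _ = filter_interactions(kept)
        assert {(r.bin_a, r.bin_b) for r in again} == keys


class TestPartners:
    def test_region_in_one_anchor_returns_other(self):
        r = record("c", 10_000, "c", 50_000, 10, 0.01)
        region = GenomicInterval("c", 11_000, 11_001)
        assert partners_of(region, [r]) == [r.bin_b]

    def test_region_outside_all_anchors_empty(self):
        r = record("c", 10_000, "c", 50_000, 10, 0.01)
        assert partners_of(GenomicInterval("c", 100_000, 100_001), [r]) == []

    def test_symmetry_and_double_loop_oracle(self):
        rng = np.random.default_rng(25)
        records = [
            record("chr1", int(rng.integers(0, 40)) * 5000,
                   "chr1", int(rng.integers(0, 40)) * 5000, 5, 0.01)
            for _ in range(60)
        ]
        records = [r for r in records if r.bin_a != r.bin_b]
        for _ in range(50):
            pos = int(rng.integers(0, 200_000))
            region = GenomicInterval("chr1", pos, pos + int(rng.integers(1, 8000)))
            expected = set()
            for r in records:
                for this, other in ((r.bin_a, r.bin_b), (r.bin_b, r.bin_a)):
                    iv = this.interval
                    if iv.chrom == region.chrom and iv.start < region.end and region.start < iv.end:
                        expected.add(other)
            assert partners_of(region, records) == sorted(expected)
        # symmetry: a contacts b <=> b contacts a
        for r in records[:10]:
            assert r.bin_b in partners_of(r.bin_a.interval, [r])
            assert r.bin_a in partners_of(r.bin_b.interval, [r])


def test_interaction_table_roundtrip():
    records = [
        record("chr1", 0, "chr1", 50_000, 7, 0.001),
        record("chr2", 5000, "chr2", 100_000, 12, 0.25),
    ]
    buf = io.StringIO()
    write_interactions(records, buf)
    buf.seek(0)
    back = read_interactions(buf)
    assert [(r.bin_a, r.bin_b, r.read_count) for r in back] == \
           [(r.bin_a, r.bin_b, r.read_count) for r in records]
    assert [r.p_value for r in back] == pytest.approx([r.p_value for r in records])
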