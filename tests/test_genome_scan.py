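"""Sliding-window scan, segment merging, coverage and BED export."""

import numpy as np
import pytest

from nucperiod import (
    GenomicSegment,
    ScanConfig,
    SymbolicFragment,
    WindowRecord,
    coverage,
    fixed_width_recoordinate,
    merge,
    planted_genome,
    read_bed,
    scan,
    write_bed,
)


def _win(chrom, start, end, p=None, dom=10):
    return WindowRecord(chrom=chrom, start=start, end=end, dominant=dom, observed_stat=1.0, p_bwb=p)


class TestScan:
    def test_window_count_10kb(self):
        frag = SymbolicFragment("chr", "C" * 10_000)
        records = scan([frag], config=ScanConfig(width=150, step=1, R=10, seed=0))
        assert len(records) == 9851

    def test_all_c_chromosome_has_no_statistic(self):
        frag = SymbolicFragment("chr", "C" * 1000)
        records = scan([frag], config=ScanConfig(width=150, step=1, R=10, seed=0))
        assert all(r.dominant is None and r.p_bwb is None for r in records)

    def test_short_chromosome_skipped(self):
        frag = SymbolicFragment("chr", "C" * 100)
        assert scan([frag], config=ScanConfig(width=150, R=10, seed=0)) == []

    def test_ambiguous_windows_skipped(self):
        frag = SymbolicFragment("chr", "N" * 200 + "C" * 200)
        records = scan([frag], config=ScanConfig(width=150, step=10, R=10, seed=0))
        starts = {r.start for r in records}
        assert 0 not in starts  # fully ambiguous window dropped
        assert 250 in starts

    def test_planted_block_windows_dominant_10(self):
        genome, blocks = planted_genome(n_blocks=1, block_length=300, spacer_length=300, base_seed=0)
        records = scan([genome], config=ScanConfig(width=150, step=5, R=30, seed=0))
        bs, be = blocks[0]
        interior = [r for r in records if r.start >= bs and r.end <= be]
        assert interior
        assert all(r.dominant == 10 for r in interior)
        assert all(r.p_bwb is not None and r.p_bwb < 0.05 for r in interior)
        spacer = [r for r in records if r.end <= bs or r.start >= be]
        assert all(r.p_bwb is None for r in spacer)

    def test_deterministic_given_seed(self):
        genome, _ = planted_genome(n_blocks=1, block_length=300, spacer_length=200, base_seed=3)
        cfg = ScanConfig(width=150, step=10, R=30, seed=9)
        a = scan([genome], config=cfg)
        b = scan([genome], config=cfg)
        assert [(r.start, r.p_bwb) for r in a] == [(r.start, r.p_bwb) for r in b]


class TestMerge:
    def test_overlapping_windows_merge(self):
        segs = merge([_win("chr1", 0, 150, 0.01), _win("chr1", 100, 250, 0.02)])
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end, segs[0].n_windows) == (0, 250, 2)
        assert segs[0].min_p_bwb == 0.01

    def test_book_ended_windows_merge(self):
        segs = merge([_win("chr1", 0, 150, 0.01), _win("chr1", 150, 300, 0.01)])
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 300)

    def test_separated_windows_stay_apart(self):
        segs = merge([_win("chr1", 0, 150, 0.01), _win("chr1", 151, 301, 0.01)])
        assert len(segs) == 2

    def test_chromosomes_never_merge(self):
        segs = merge([_win("chr1", 0, 150, 0.01), _win("chr2", 0, 150, 0.01)])
        assert len(segs) == 2

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            merge([_win("chr1", 100, 250, 0.01), _win("chr1", 0, 150, 0.01)])

    def test_flag_mode_flags_segments_with_significant_window(self):
        segs = merge(
            [_win("chr1", 0, 150, 0.5), _win("chr1", 100, 250, 0.01), _win("chr1", 500, 650, 0.5)],
            alpha=0.05,
            mode="flag",
        )
        assert [s.significant for s in segs] == [True, False]

    def test_significant_mode_keeps_only_significant(self):
        segs = merge(
            [_win("chr1", 0, 150, 0.5), _win("chr1", 100, 250, 0.01)],
            alpha=0.05,
            mode="significant",
        )
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (100, 250)

    def test_idempotent(self):
        segs = merge([_win("chr1", 0, 150, 0.01), _win("chr1", 100, 250, 0.02)])
        again = merge(
            [
                WindowRecord(s.chrom, s.start, s.end, 10, 1.0, s.min_p_bwb)
                for s in segs
            ]
        )
        assert [(s.start, s.end) for s in again] == [(s.start, s.end) for s in segs]


class TestCoverage:
    def test_fraction(self):
        seg = GenomicSegment("chr1", 0, 250, 2, 0.01, True)
        cov = coverage([seg], {"chr1": 1000})
        assert cov["chr1"] == 0.25
        assert cov["total"] == 0.25

    def test_empty_is_zero(self):
        assert coverage([], {"chr1": 1000})["total"] == 0.0

    def test_full_tiling_is_one(self):
        segs = [
            GenomicSegment("chr1", 0, 500, 1, 0.01, True),
            GenomicSegment("chr1", 500, 1000, 1, 0.01, True),
        ]
        assert coverage(segs, {"chr1": 1000})["chr1"] == 1.0

    def test_order_invariant(self):
        segs = [
            GenomicSegment("chr1", 500, 1000, 1, 0.01, True),
            GenomicSegment("chr1", 0, 250, 1, 0.01, True),
        ]
        assert coverage(segs, {"chr1": 1000})["total"] == coverage(segs[::-1], {"chr1": 1000})["total"]


class TestBed:
    def test_exact_line_format(self, tmp_path):
        path = tmp_path / "out.bed"
        write_bed([GenomicSegment("chr1", 0, 250, 2, 0.004, True)], path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("#")
        assert lines[1] == "chr1\t0\t250\tP=0.004"

    def test_empty_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_bed([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("#")
        assert read_bed(path) == []

    def test_round_trip(self, tmp_path):
        segs = [
            GenomicSegment("chr1", 10, 260, 3, 0.004, True),
            GenomicSegment("chr2", 0, 150, 1, None, False),
        ]
        path = tmp_path / "rt.bed"
        write_bed(segs, path)
        rows = read_bed(path)
        assert [(r[0], r[1], r[2]) for r in rows] == [("chr1", 10, 260), ("chr2", 0, 150)]
        assert rows[0][3] == "P=0.004"
        assert rows[1][3] == "P=NA"

    def test_strict_reader_rejects_bad_lines(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t10\t5\tP=1\n")
        with pytest.raises(ValueError):
            read_bed(path)


class TestFixedWidthRecoordinate:
    def test_even_expansion(self):
        assert fixed_width_recoordinate([("chr1", 100, 200)], 150) == [("chr1", 75, 225)]

    def test_odd_expansion_biased_5prime(self):
        assert fixed_width_recoordinate([("chr1", 100, 249)], 150) == [("chr1", 99, 249)]

    def test_contraction(self):
        out = fixed_width_recoordinate([("chr1", 100, 300)], 150)
        assert out == [("chr1", 125, 275)]

    def test_overlapping_adjusted_intervals_both_dropped(self):
        out = fixed_width_recoordinate([("chr1", 100, 200), ("chr1", 260, 360)], 150)
        # adjusted: (75, 225) and (235, 385): no overlap -> both kept
        assert len(out) == 2
        out = fixed_width_recoordinate([("chr1", 100, 200), ("chr1", 240, 340)], 150)
        # adjusted: (75, 225) and (215, 365): overlap -> both dropped
        assert out == []

    def test_out_of_bounds_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            out = fixed_width_recoordinate([("chr1", 10, 60)], 150)
        assert out == []

    def test_chrom_size_bound(self):
        with pytest.warns(UserWarning):
            out = fixed_width_recoordinate([("chr1", 900, 960)], 150, {"chr1": 1000})
        assert out == []
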