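"""Bin-grid construction, BED/bigWig round trips, blacklist and count filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import binsig as bs
from binsig.core import FormatError, GridMismatchError

from conftest import grid_from_rows, write_bed


class TestGridAndIntervals:
    def test_interval_invariants(self):
        with pytest.raises(FormatError):
            bs.GenomicInterval("chr1", 5, 5)
        with pytest.raises(FormatError):
            bs.GenomicInterval("chr1", -1, 5)
        with pytest.raises(FormatError):
            bs.GenomicInterval("", 0, 5)

    def test_overlapping_bins_rejected(self):
        with pytest.raises(FormatError, match="overlap"):
            grid_from_rows([("chr1", 0, 10_000), ("chr1", 5_000, 15_000)])

    def test_mixed_widths_rejected_except_chromosome_end(self):
        with pytest.raises(FormatError, match="width"):
            grid_from_rows([("chr1", 0, 10_000), ("chr1", 10_000, 12_000),
                            ("chr1", 12_000, 22_000)])
        # remainder bin at the end of a chromosome is allowed
        g = grid_from_rows([("chr1", 0, 10_000), ("chr1", 10_000, 15_000),
                            ("chr2", 0, 10_000)])
        assert g.bin_width == 10_000

    def test_bins_sorted_on_construction(self):
        g = grid_from_rows([("chr2", 0, 10_000), ("chr1", 10_000, 20_000),
                            ("chr1", 0, 10_000)])
        assert list(g.chroms) == ["chr1", "chr1", "chr2"]
        assert list(g.starts) == [0, 10_000, 0]


class TestReadBinnedBed:
    def test_three_line_example(self, tmp_path):
        p = write_bed(tmp_path / "a.bed", [
            ("chr1", 0, 10_000, 5), ("chr1", 10_000, 20_000, 0),
            ("chr2", 0, 10_000, 7)])
        t = bs.read_binned_bed(p)
        assert t.grid.n_bins == 3
        assert list(t.counts) == [5.0, 0.0, 7.0]
        assert t.grid.bin_width == 10_000

    def test_overlapping_rows_error(self, tmp_path):
        p = write_bed(tmp_path / "a.bed", [
            ("chr1", 0, 10_000, 1), ("chr1", 5_000, 15_000, 2)])
        with pytest.raises(FormatError, match="overlap"):
            bs.read_binned_bed(p)

    def test_missing_count_column_is_error_not_zeros(self, tmp_path):
        p = write_bed(tmp_path / "a.bed", [("chr1", 0, 10_000),
                                           ("chr1", 10_000, 20_000)])
        with pytest.raises(FormatError, match="column"):
            bs.read_binned_bed(p)

    def test_non_numeric_count_reports_line(self, tmp_path):
        p = write_bed(tmp_path / "a.bed", [
            ("chr1", 0, 10_000, 5), ("chr1", 10_000, 20_000, "x")])
        with pytest.raises(FormatError, match="line 2"):
            bs.read_binned_bed(p)

    def test_bed_round_trip(self, tmp_path):
        p = write_bed(tmp_path / "a.bed", [
            ("chr1", 0, 10_000, 5), ("chr1", 10_000, 20_000, 0),
            ("chr2", 0, 10_000, 7)])
        t = bs.read_binned_bed(p, sample_id="a")
        out = tmp_path / "out.bed"
        bs.write_binned_bed(t, out)
        t2 = bs.read_binned_bed(out, sample_id="a")
        assert t.grid.same_as(t2.grid)
        np.testing.assert_array_equal(t.counts, t2.counts)


class TestAlignTrackset:
    def test_two_identical_grids(self, tmp_path):
        rows = [("chr1", 0, 100, 1), ("chr1", 100, 200, 2)]
        t1 = bs.read_binned_bed(write_bed(tmp_path / "a.bed", rows), sample_id="a")
        t2 = bs.read_binned_bed(write_bed(tmp_path / "b.bed", rows), sample_id="b")
        ts = bs.align_trackset([t1, t2])
        assert ts.n_samples == 2

    def test_single_track_identity(self, small_trackset):
        ts = bs.align_trackset([small_trackset.tracks[0]])
        assert ts.n_samples == 1

    def test_grid_mismatch_names_bin(self, tmp_path):
        t1 = bs.read_binned_bed(write_bed(tmp_path / "a.bed",
                                          [("chr1", 0, 100, 1),
                                           ("chr1", 100, 200, 1)]), sample_id="a")
        t2 = bs.read_binned_bed(write_bed(tmp_path / "b.bed",
                                          [("chr1", 0, 50, 1),
                                           ("chr1", 50, 100, 1)]), sample_id="b")
        with pytest.raises(GridMismatchError, match="bin 0"):
            bs.align_trackset([t1, t2])


class TestBlacklist:
    def test_single_bp_overlap_removes_both_flanking_bins(self):
        grid = grid_from_rows([("chr1", 0, 10_000), ("chr1", 10_000, 20_000),
                               ("chr1", 20_000, 30_000)])
        ts = bs.TrackSet(grid, [bs.SampleTrack("s", [1.0, 2.0, 3.0], grid)])
        out = bs.apply_blacklist(ts, [bs.GenomicInterval("chr1", 9_999, 10_001)])
        assert list(out.grid.starts) == [20_000]

    def test_full_removal_is_error(self):
        grid = grid_from_rows([("chr1", 0, 10_000), ("chr1", 10_000, 20_000)])
        ts = bs.TrackSet(grid, [bs.SampleTrack("s", [1.0, 2.0], grid)])
        with pytest.raises(FormatError, match="every bin"):
            bs.apply_blacklist(ts, [bs.GenomicInterval("chr1", 9_999, 10_001)])

    def test_absent_chromosome_no_change(self, small_trackset):
        out = bs.apply_blacklist(small_trackset,
                                 [bs.GenomicInterval("chrX", 0, 1_000_000)])
        assert out.grid.n_bins == small_trackset.grid.n_bins

    def test_idempotent(self, small_trackset):
        bl = [bs.GenomicInterval("chr1", 9_999, 10_001)]
        once = bs.apply_blacklist(small_trackset, bl)
        twice = bs.apply_blacklist(once, bl)
        assert once.grid.same_as(twice.grid)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_matches_bruteforce_overlap_scan(self, seed):
        """Surviving bins are exactly those with zero pairwise overlap
        against every blacklist interval (O(n*m) reference scan)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        starts = np.arange(n) * 100
        grid = grid_from_rows([("chr1", int(s), int(s) + 100) for s in starts])
        ts = bs.TrackSet(grid, [bs.SampleTrack("s", np.ones(n), grid)])
        m = int(rng.integers(1, 20))
        bl = []
        for _ in range(m):
            s = int(rng.integers(0, n * 100))
            bl.append(bs.GenomicInterval("chr1", s, s + int(rng.integers(1, 500))))
        expected_keep = []
        for i in range(n):
            b0, b1 = starts[i], starts[i] + 100
            hit = any(max(b0, iv.start) < min(b1, iv.end) for iv in bl)
            expected_keep.append(not hit)
        expected_keep = np.array(expected_keep)
        if not expected_keep.any():
            with pytest.raises(FormatError):
                bs.apply_blacklist(ts, bl)
            return
        out = bs.apply_blacklist(ts, bl)
        np.testing.assert_array_equal(out.grid.starts, starts[expected_keep])


class TestFilterLowCount:
    def test_examples(self, conftest=None):
        grid = grid_from_rows([("chr1", 0, 100), ("chr1", 100, 200),
                               ("chr1", 200, 300)])
        ts = bs.TrackSet(grid, [
            bs.SampleTrack("a", [0.0, 3.0, 1.0], grid),
            bs.SampleTrack("b", [0.0, 0.0, 2.0], grid)])
        out = bs.filter_low_count(ts, min_total=1)
        assert out.grid.n_bins == 2
        assert bs.filter_low_count(ts, min_total=0).grid.n_bins == 3
        with pytest.raises(FormatError):
            bs.filter_low_count(ts, min_total=10)

    def test_threshold_monotone(self, small_trackset):
        kept = []
        for t in (0, 1, 3, 8):
            try:
                out = bs.filter_low_count(small_trackset, min_total=t)
                kept.append(set(map(tuple, out.grid.to_dataframe().values)))
            except FormatError:
                kept.append(set())
        for a, b in zip(kept, kept[1:]):
            assert b <= a


class TestBigWig:
    def test_round_trip_within_float32(self, tmp_path, small_grid):
        values = np.array([0.123456, 7.5, 0.0, 3.25, 9.875])
        track = bs.NormalizedTrack("s", values, small_grid)
        sizes = bs.ChromSizes({"chr1": 40_000, "chr2": 30_000})
        p = tmp_path / "t.bw"
        bs.write_bigwig(track, sizes, p)
        back = bs.read_bigwig_bins(p, small_grid)
        np.testing.assert_allclose(back.values, values, atol=1e-4)

    def test_bin_exceeding_chromosome_errors(self, small_grid):
        track = bs.NormalizedTrack("s", np.ones(5), small_grid)
        with pytest.raises(FormatError, match="exceeds"):
            bs.write_bigwig(track, bs.ChromSizes({"chr1": 15_000,
                                                  "chr2": 30_000}), "x.bw")

    def test_missing_chromosome_in_sizes(self, small_grid):
        track = bs.NormalizedTrack("s", np.ones(5), small_grid)
        with pytest.raises(FormatError, match="missing"):
            bs.write_bigwig(track, bs.ChromSizes({"chr1": 40_000}), "x.bw")

    def test_uncovered_chromosome_reads_zero_with_warning(self, tmp_path):
        grid1 = grid_from_rows([("chr1", 0, 100), ("chr1", 100, 200)])
        track = bs.NormalizedTrack("s", [1.5, 2.5], grid1)
        p = tmp_path / "t.bw"
        bs.write_bigwig(track, bs.ChromSizes({"chr1": 200}), p)
        grid2 = grid_from_rows([("chr1", 0, 100), ("chr2", 0, 100)])
        with pytest.warns(UserWarning, match="not covered"):
            back = bs.read_bigwig_bins(p, grid2)
        np.testing.assert_allclose(back.values, [1.5, 0.0], atol=1e-4)

    def test_unreadable_file(self, tmp_path, small_grid):
        p = tmp_path / "junk.bw"
        p.write_text("not a bigwig")
        with pytest.raises(OSError):
            bs.read_bigwig_bins(p, small_grid)
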