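"""Reading and writing binned genomic signal (BED in, bigWig out).

BED files are tab-delimited with no header; the count lives in a
configurable column (default column 4, where binned-coverage exporters
place values). bigWig output uses pyBigWig with one fixed-step-free entry
per bin, and bigWig input samples each bin as the mean over its interval.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import pyBigWig

from .core import (
    BinGrid,
    ChromSizes,
    FormatError,
    GenomicInterval,
    GridMismatchError,
    NormalizedTrack,
    SampleTrack,
    TrackSet,
)

log = logging.getLogger(__name__)


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read a BED3(+) file as a list of intervals (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str}, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]


def read_binned_bed(path, count_column: int = 4, sample_id: str | None = None,
                    condition: str = "", replicate: str = "") -> SampleTrack:
    """Parse a binned-count BED file into a :class:`SampleTrack`.

    Parameters
    ----------
    count_column
        1-based BED column holding the per-bin count (default 4, i.e. the
        column right after chrom/start/end).
    """
    if count_column < 4:
        raise ValueError("count_column must be >= 4 (after chrom/start/end)")
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty BED file") from None
    if df.shape[1] < count_column:
        raise FormatError(
            f"{path}: expected a count in column {count_column} but file has "
            f"only {df.shape[1]} columns"
        )
    chroms = df[0].to_numpy(dtype=object)
    try:
        starts = df[1].to_numpy(dtype=np.int64)
        ends = df[2].to_numpy(dtype=np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer coordinate ({exc})") from None
    raw = pd.to_numeric(df[count_column - 1], errors="coerce").to_numpy()
    if np.any(np.isnan(raw)):
        line = int(np.flatnonzero(np.isnan(raw))[0]) + 1
        raise FormatError(
            f"{path}: non-numeric count {df[count_column - 1][line - 1]!r} "
            f"on line {line}"
        )
    if np.any(raw < 0):
        line = int(np.flatnonzero(raw < 0)[0]) + 1
        raise FormatError(f"{path}: negative count on line {line}")
    order = np.lexsort((starts, chroms.astype(str)))
    grid = BinGrid.from_arrays(chroms[order], starts[order], ends[order])
    if sample_id is None:
        sample_id = str(path)
    return SampleTrack(sample_id=sample_id, counts=raw[order], grid=grid,
                       condition=condition, replicate=replicate)


def write_binned_bed(track, path) -> None:
    """Write a track back out as BED (chrom, start, end, value)."""
    values = track.counts if isinstance(track, SampleTrack) else track.values
    df = track.grid.to_dataframe()
    df["value"] = values
    df.to_csv(path, sep="\t", header=False, index=False)


def align_trackset(tracks: Sequence[SampleTrack]) -> TrackSet:
    """Combine tracks into a :class:`TrackSet`, verifying identical grids."""
    if len(tracks) == 0:
        raise ValueError("need at least one track")
    grid = tracks[0].grid
    for t in tracks[1:]:
        if not t.grid.same_as(grid):
            raise GridMismatchError(
                f"track {t.sample_id!r} does not share the grid of "
                f"{tracks[0].sample_id!r}: first difference at "
                f"{t.grid.first_difference(grid)}"
            )
    return TrackSet(grid, list(tracks))


def apply_blacklist(ts: TrackSet, blacklist: Sequence[GenomicInterval]) -> TrackSet:
    """Drop every bin overlapping a blacklist interval by >= 1 bp."""
    overlap = ts.grid.overlap_bases(list(blacklist))
    keep = overlap == 0
    removed = int((~keep).sum())
    if not keep.any():
        raise FormatError("blacklist removes every bin in the grid")
    log.info("blacklist: removed %d of %d bins", removed, ts.grid.n_bins)
    if removed == 0:
        return ts
    return ts.subset_bins(keep)


def filter_low_count(ts: TrackSet, min_total: float = 1.0) -> TrackSet:
    """Drop bins whose raw count summed across all tracks is < ``min_total``.

    The default of 1 removes only bins with zero signal in every sample, so
    bins present in a single condition (exactly the differential ones) are
    kept.
    """
    totals = ts.matrix().sum(axis=1)
    keep = totals >= min_total
    if not keep.any():
        raise FormatError(
            f"low-count filter (min_total={min_total}) removes every bin"
        )
    removed = int((~keep).sum())
    log.info("low-count filter: removed %d of %d bins", removed, ts.grid.n_bins)
    if removed == 0:
        return ts
    return ts.subset_bins(keep)


def write_bigwig(track, sizes: ChromSizes, path) -> None:
    """Write one value per bin interval to a standard bigWig file."""
    grid = track.grid
    values = track.counts if isinstance(track, SampleTrack) else track.values
    if grid.n_bins == 0:
        raise FormatError("cannot write an empty track to bigWig")
    chrom_order = list(dict.fromkeys(grid.chroms.astype(str)))
    for chrom in chrom_order:
        if chrom not in sizes:
            raise FormatError(f"chromosome {chrom!r} missing from sizes table")
        max_end = int(grid.ends[grid.chroms == chrom].max())
        if max_end > sizes[chrom]:
            raise FormatError(
                f"bin end {max_end} exceeds length {sizes[chrom]} of {chrom!r}"
            )
    bw = pyBigWig.open(str(path), "w")
    try:
        bw.addHeader([(c, int(sizes[c])) for c in chrom_order])
        bw.addEntries(
            [str(c) for c in grid.chroms],
            [int(s) for s in grid.starts],
            ends=[int(e) for e in grid.ends],
            values=[float(v) for v in values],
        )
    finally:
        bw.close()


def read_bigwig_bins(path, grid: BinGrid) -> NormalizedTrack:
    """Sample a bigWig as the per-bin mean over each grid interval.

    Bins (or whole chromosomes) not covered by the file yield 0 with a
    warning; bigWig stores 32-bit floats, so round trips are exact only to
    float32 precision.
    """
    try:
        bw = pyBigWig.open(str(path))
    except RuntimeError as exc:
        raise OSError(f"cannot read bigWig {path}: {exc}") from None
    values = np.zeros(grid.n_bins, dtype=np.float64)
    uncovered = 0
    try:
        bw_chroms = bw.chroms()
        for chrom in dict.fromkeys(grid.chroms.astype(str)):
            mask = grid.chroms == chrom
            if chrom not in bw_chroms:
                uncovered += int(mask.sum())
                continue
            starts = grid.starts[mask]
            ends = np.minimum(grid.ends[mask], bw_chroms[chrom])
            lo, hi = int(starts.min()), int(ends.max())
            span = np.asarray(bw.values(chrom, lo, hi), dtype=np.float64)
            nan = np.isnan(span)
            span[nan] = 0.0
            cum = np.concatenate([[0.0], np.cumsum(span)])
            cov = np.concatenate([[0], np.cumsum(~nan)])
            sums = cum[ends - lo] - cum[starts - lo]
            covered = cov[ends - lo] - cov[starts - lo]
            means = np.where(covered > 0, sums / np.maximum(covered, 1), 0.0)
            uncovered += int((covered == 0).sum())
            values[mask] = means
    finally:
        bw.close()
    if uncovered:
        warnings.warn(
            f"{path}: {uncovered} grid bins not covered by the bigWig; "
            "set to 0"
        )
    return NormalizedTrack(sample_id=str(path), values=values, grid=grid)
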