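"""Shared coordinate frame and in-memory containers for binned genomic signal.

All coordinates follow BED semantics: 0-based, half-open ``[start, end)``.
A :class:`BinGrid` is the single source of truth for bin coordinates; every
track (raw or normalized) refers to one grid, and multi-sample containers
require their members to share it bin-for-bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input data (bad BED rows, inconsistent bins, ...)."""


class GridMismatchError(ValueError):
    """Operation combining tracks whose bin grids differ."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise FormatError("interval chromosome name is empty")
        if self.start < 0:
            raise FormatError(f"interval start {self.start} < 0")
        if self.end <= self.start:
            raise FormatError(
                f"interval end {self.end} must exceed start {self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start


class ChromSizes(dict):
    """Mapping of chromosome name to its length in base pairs."""

    def __init__(self, mapping: Mapping[str, int]):
        super().__init__()
        for name, length in mapping.items():
            length = int(length)
            if length <= 0:
                raise FormatError(f"chromosome {name!r} has non-positive length")
            self[name] = length

    @classmethod
    def from_tsv(cls, path) -> "ChromSizes":
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                         names=["chrom", "length"], dtype={"chrom": str})
        return cls(dict(zip(df["chrom"], df["length"])))


@dataclass(frozen=True)
class BinGrid:
    """Ordered, non-overlapping uniform windows shared by a set of tracks.

    Windows are sorted by (chrom, start) and all have width ``bin_width``
    except possibly the final window of a chromosome, which may be the
    chromosome-end remainder.
    """

    chroms: np.ndarray          # str per bin
    starts: np.ndarray          # int64
    ends: np.ndarray            # int64
    bin_width: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chroms", np.asarray(self.chroms, dtype=object))
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=np.int64))
        object.__setattr__(self, "ends", np.asarray(self.ends, dtype=np.int64))

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def __len__(self) -> int:
        return self.n_bins

    @classmethod
    def from_arrays(cls, chroms, starts, ends) -> "BinGrid":
        """Build a grid from raw coordinate arrays, validating the invariants."""
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if len(starts) == 0:
            raise FormatError("empty bin grid")
        if np.any(starts < 0) or np.any(ends <= starts):
            bad = int(np.flatnonzero((starts < 0) | (ends <= starts))[0])
            raise FormatError(
                f"invalid interval at row {bad}: "
                f"{chroms[bad]}:{starts[bad]}-{ends[bad]}"
            )
        order = np.lexsort((starts, chroms.astype(str)))
        chroms, starts, ends = chroms[order], starts[order], ends[order]
        same_chrom = chroms[1:] == chroms[:-1]
        if np.any(same_chrom & (starts[1:] < ends[:-1])):
            bad = int(np.flatnonzero(same_chrom & (starts[1:] < ends[:-1]))[0])
            raise FormatError(
                f"overlapping bins: {chroms[bad]}:{starts[bad]}-{ends[bad]} and "
                f"{chroms[bad + 1]}:{starts[bad + 1]}-{ends[bad + 1]}"
            )
        widths = ends - starts
        bin_width = int(np.max(widths))
        # every non-final-per-chromosome bin must have the modal width
        is_last = np.ones(len(starts), dtype=bool)
        is_last[:-1] = ~same_chrom
        if np.any(widths[~is_last] != bin_width):
            bad = int(np.flatnonzero(~is_last)[np.flatnonzero(widths[~is_last] != bin_width)[0]])
            raise FormatError(
                f"mixed bin widths: bin {chroms[bad]}:{starts[bad]}-{ends[bad]} "
                f"has width {widths[bad]}, expected {bin_width}"
            )
        return cls(chroms, starts, ends, bin_width)

    def same_as(self, other: "BinGrid") -> bool:
        return (
            self.n_bins == other.n_bins
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
            and np.array_equal(self.chroms, other.chroms)
        )

    def first_difference(self, other: "BinGrid") -> str:
        """Human-readable description of the first differing bin."""
        if self.n_bins != other.n_bins:
            return f"bin counts differ ({self.n_bins} vs {other.n_bins})"
        diff = (
            (self.chroms != other.chroms)
            | (self.starts != other.starts)
            | (self.ends != other.ends)
        )
        i = int(np.flatnonzero(diff)[0])
        return (
            f"bin {i}: {self.chroms[i]}:{self.starts[i]}-{self.ends[i]} vs "
            f"{other.chroms[i]}:{other.starts[i]}-{other.ends[i]}"
        )

    def subset(self, mask: np.ndarray) -> "BinGrid":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise FormatError("operation would leave an empty bin grid")
        return BinGrid(self.chroms[mask], self.starts[mask], self.ends[mask],
                       self.bin_width)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms.astype(str), "start": self.starts, "end": self.ends}
        )

    def overlap_bases(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        """Per-bin number of bases overlapped by a set of intervals.

        The intervals are merged per chromosome first, so double-covered
        bases count once.
        """
        out = np.zeros(self.n_bins, dtype=np.int64)
        merged = merge_intervals(intervals) if intervals else []
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            mask = self.chroms == chrom
            if not mask.any():
                continue
            s = np.array([iv.start for iv in ivs], dtype=np.int64)
            e = np.array([iv.end for iv in ivs], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(e - s)])

            def coverage_below(x: np.ndarray) -> np.ndarray:
                j = np.searchsorted(s, x, side="right") - 1
                inside = np.clip(x - s[np.clip(j, 0, None)], 0,
                                 (e - s)[np.clip(j, 0, None)])
                inside[j < 0] = 0
                return cum[np.clip(j, 0, None)] + inside

            out[mask] = coverage_below(self.ends[mask]) - coverage_below(
                self.starts[mask]
            )
        return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals into a sorted disjoint set."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass
class SampleTrack:
    """One sample's raw per-bin read counts on a :class:`BinGrid`."""

    sample_id: str
    counts: np.ndarray
    grid: BinGrid
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if len(self.counts) != self.grid.n_bins:
            raise GridMismatchError(
                f"track {self.sample_id!r}: {len(self.counts)} counts for "
                f"{self.grid.n_bins} bins"
            )
        if np.any(self.counts < 0):
            raise FormatError(f"track {self.sample_id!r} has negative counts")

    @property
    def library_size(self) -> float:
        return float(self.counts.sum())


@dataclass
class NormalizedTrack:
    """Per-bin normalized (and possibly scaled / log-transformed) signal.

    ``space`` records whether values are on a linear or log2 scale so that a
    track is never log-transformed twice.
    """

    sample_id: str
    values: np.ndarray
    grid: BinGrid
    space: str = "linear"           # {"linear", "log2"}
    pseudocount: float = 0.0
    condition: str = ""
    replicate: str = ""
    source_ids: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != self.grid.n_bins:
            raise GridMismatchError(
                f"track {self.sample_id!r}: {len(self.values)} values for "
                f"{self.grid.n_bins} bins"
            )
        if self.space not in ("linear", "log2"):
            raise ValueError(f"unknown value space {self.space!r}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError(f"track {self.sample_id!r} has non-finite values")


@dataclass
class TrackSet:
    """A bin grid plus one or more tracks defined on it."""

    grid: BinGrid
    tracks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.sample_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids: {ids}")
        for t in self.tracks:
            if not t.grid.same_as(self.grid):
                raise GridMismatchError(
                    f"track {t.sample_id!r} grid differs: "
                    f"{t.grid.first_difference(self.grid)}"
                )

    @property
    def sample_ids(self) -> list:
        return [t.sample_id for t in self.tracks]

    @property
    def n_samples(self) -> int:
        return len(self.tracks)

    def matrix(self) -> np.ndarray:
        """bins x samples matrix of the tracks' values/counts."""
        cols = [
            t.counts if isinstance(t, SampleTrack) else t.values
            for t in self.tracks
        ]
        return np.column_stack(cols)

    def subset_bins(self, mask: np.ndarray) -> "TrackSet":
        grid = self.grid.subset(mask)
        new_tracks = []
        for t in self.tracks:
            if isinstance(t, SampleTrack):
                new_tracks.append(replace(t, counts=t.counts[mask], grid=grid))
            else:
                new_tracks.append(replace(t, values=t.values[mask], grid=grid))
        return TrackSet(grid, new_tracks)
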