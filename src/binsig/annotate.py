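"""Genic/intergenic classification of bins and two-sample scatter data.

The genic compartment is the merged union of gene intervals (strand
ignored); intergenic is its complement. A bin is called genic when at
least a configurable fraction (default half) of its bases fall inside the
union; the boundary case resolves to genic. Scatter data pairs two log2
tracks per bin with the class label, the raw material for the
genic/intergenic scatterplot and for density clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BinGrid, GenomicInterval, GridMismatchError, NormalizedTrack, merge_intervals


@dataclass
class GenicUnion:
    """Merged, sorted, disjoint gene intervals."""

    intervals: list

    def __post_init__(self) -> None:
        if len(self.intervals) == 0:
            raise ValueError("genic union is empty")

    @property
    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)


@dataclass
class BinClassification:
    """Per-bin genic/intergenic label plus the underlying overlap fraction."""

    labels: np.ndarray            # "genic" / "intergenic" per bin
    overlap_fraction: np.ndarray
    threshold: float

    @property
    def genic_mask(self) -> np.ndarray:
        return self.labels == "genic"


def build_genic_union(gene_intervals: Sequence[GenomicInterval]) -> GenicUnion:
    """Merge gene intervals (overlapping or book-ended) into the genic union."""
    if len(gene_intervals) == 0:
        raise ValueError("no gene intervals supplied")
    return GenicUnion(merge_intervals(gene_intervals))


def read_gene_intervals(path) -> list[GenomicInterval]:
    """Gene intervals from BED or from GFF3/GTF rows with feature type 'gene'.

    GFF/GTF coordinates are 1-based inclusive and are converted to BED
    half-open. Strand is ignored throughout.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3", ".gtf")):
        ivs = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5 or parts[2] != "gene":
                    continue
                ivs.append(GenomicInterval(parts[0], int(parts[3]) - 1,
                                           int(parts[4])))
        if not ivs:
            raise ValueError(f"{path}: no 'gene' records found")
        return ivs
    from .io import read_bed_intervals
    return read_bed_intervals(path)


def classify_bins(grid: BinGrid, union: GenicUnion,
                  threshold: float = 0.5) -> BinClassification:
    """Label each bin genic iff its genic overlap fraction is >= threshold."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    overlap = grid.overlap_bases(union.intervals)
    frac = overlap / (grid.ends - grid.starts)
    labels = np.where(frac >= threshold, "genic", "intergenic").astype(object)
    return BinClassification(labels=labels, overlap_fraction=frac,
                             threshold=threshold)


def scatter_data(a: NormalizedTrack, b: NormalizedTrack,
                 cls: BinClassification | None = None) -> pd.DataFrame:
    """Per-bin (x, y, class) points for a two-sample comparison.

    ``x`` is sample ``a`` (e.g. wildtype), ``y`` is sample ``b`` (e.g.
    treated); both must be log2-space tracks on the same grid.
    """
    if not a.grid.same_as(b.grid):
        raise GridMismatchError("scatter tracks are on different grids")
    if a.space != "log2" or b.space != "log2":
        raise ValueError("scatter data expects log2-space tracks")
    df = a.grid.to_dataframe()
    df["x"] = a.values
    df["y"] = b.values
    if cls is not None:
        if len(cls.labels) != a.grid.n_bins:
            raise GridMismatchError("classification does not match the grid")
        df["class"] = cls.labels
    return df


def scatter_plot(points: pd.DataFrame, path, x_label: str = "sample A",
                 y_label: str = "sample B") -> None:
    """Two-color genic/intergenic scatter with the identity diagonal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"genic": "#1f77b4", "intergenic": "#d62728"}
    if "class" in points:
        for label, sub in points.groupby("class", sort=True):
            ax.scatter(sub["x"], sub["y"], s=2, alpha=0.4,
                       color=colors.get(label, "gray"), label=str(label),
                       rasterized=True)
        ax.legend(markerscale=5, frameon=False)
    else:
        ax.scatter(points["x"], points["y"], s=2, alpha=0.4, color="gray",
                   rasterized=True)
    lims = [min(points["x"].min(), points["y"].min()),
            max(points["x"].max(), points["y"].max())]
    ax.plot(lims, lims, color="black", lw=0.8, ls="--")
    ax.set_xlabel(x_label)
    ax.set_ylabel(y_label)
    fig.tight_layout()
    fig.savefig(path, metadata=_figure_metadata(path))
    plt.close(fig)


def _figure_metadata(path) -> dict | None:
    """Strip creation timestamps so figure output is byte-reproducible."""
    p = str(path).lower()
    if p.endswith(".png"):
        return {"Software": None}
    if p.endswith(".pdf"):
        return {"CreationDate": None}
    if p.endswith(".svg"):
        return {"Date": None}
    return None
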