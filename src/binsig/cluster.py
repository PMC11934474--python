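"""Density-based clustering of bins in the two-sample log-signal plane.

Bins are clustered on their (x, y) log2-signal coordinates — the same
points shown in the scatterplots — with HDBSCAN, independent of any
differential-binding status. Low-density bins are noise; surviving
clusters are lettered A, B, C, ... deterministically by descending size,
ties broken by ascending centroid x then y. ``min_samples`` is the
conservativeness dial: the larger it is, the more points end up as noise.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

from .core import BinGrid

NOISE = "noise"


@dataclass
class ClusterParams:
    min_cluster_size: int = 100
    min_samples: int | None = None     # None -> HDBSCAN default (= min_cluster_size)
    cluster_selection_method: str = "eom"
    seed: int = 0                      # only for subsampling plotted points

    def __post_init__(self) -> None:
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.min_samples is not None and self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass
class ClusterAssignment:
    """Per-bin cluster letter (or ``noise``) plus per-cluster summaries."""

    labels: np.ndarray            # letters / "noise", one per point
    summary: pd.DataFrame         # letter, size, centroid_x, centroid_y

    @property
    def letters(self) -> list:
        return list(self.summary["letter"])

    def mask(self, letter: str) -> np.ndarray:
        if letter != NOISE and letter not in self.letters:
            raise KeyError(f"no cluster {letter!r}; have {self.letters}")
        return self.labels == letter


def cluster_bins(points: pd.DataFrame, params: ClusterParams | None = None,
                 ) -> ClusterAssignment:
    """HDBSCAN over the (x, y) columns of a scatter-data table."""
    params = params or ClusterParams()
    xy = points[["x", "y"]].to_numpy(dtype=float)
    n = len(xy)
    if n < params.min_cluster_size:
        warnings.warn(
            f"{n} points is fewer than min_cluster_size="
            f"{params.min_cluster_size}; every bin labeled noise"
        )
        return ClusterAssignment(
            labels=np.full(n, NOISE, dtype=object),
            summary=pd.DataFrame(columns=["letter", "size", "centroid_x",
                                          "centroid_y"]),
        )
    model = HDBSCAN(
        min_cluster_size=params.min_cluster_size,
        min_samples=params.min_samples,
        cluster_selection_method=params.cluster_selection_method,
    )
    raw = model.fit_predict(xy)
    ids = [c for c in np.unique(raw) if c >= 0]
    if len(ids) > 26:
        raise ValueError(
            f"{len(ids)} clusters exceed the 26 letters A-Z; raise "
            "min_cluster_size or min_samples"
        )
    stats = []
    for c in ids:
        m = raw == c
        stats.append((c, int(m.sum()), float(xy[m, 0].mean()),
                      float(xy[m, 1].mean())))
    # letters by descending size, ties by ascending centroid x then y
    stats.sort(key=lambda t: (-t[1], t[2], t[3]))
    letter_of = {c: string.ascii_uppercase[i]
                 for i, (c, *_rest) in enumerate(stats)}
    labels = np.array([letter_of.get(c, NOISE) for c in raw], dtype=object)
    summary = pd.DataFrame(
        [(letter_of[c], size, cx, cy) for c, size, cx, cy in stats],
        columns=["letter", "size", "centroid_x", "centroid_y"],
    )
    return ClusterAssignment(labels=labels, summary=summary)


def export_cluster_bed(assign: ClusterAssignment, grid: BinGrid,
                       letter: str, path) -> int:
    """Write one cluster's (or the noise set's) bins as a sorted BED4 file."""
    mask = assign.mask(letter)
    df = grid.to_dataframe()[mask]
    df["name"] = letter
    df.to_csv(path, sep="\t", header=False, index=False)
    return int(mask.sum())


def density_plot(points: pd.DataFrame, assign: ClusterAssignment, path,
                 max_points: int = 50000, seed: int = 0) -> None:
    """2-D density scatter with clusters colored and lettered at centroids."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .annotate import _figure_metadata

    xy = points[["x", "y"]].to_numpy(dtype=float)
    labels = assign.labels
    if len(xy) > max_points:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(xy), size=max_points, replace=False))
        xy, labels = xy[idx], labels[idx]
    fig, ax = plt.subplots(figsize=(5.5, 5))
    noise_mask = labels == NOISE
    ax.scatter(xy[noise_mask, 0], xy[noise_mask, 1], s=2, alpha=0.2,
               color="lightgray", rasterized=True, label=None)
    cmap = plt.get_cmap("tab10")
    for i, row in assign.summary.iterrows():
        m = labels == row["letter"]
        ax.scatter(xy[m, 0], xy[m, 1], s=2, alpha=0.4,
                   color=cmap(i % 10), rasterized=True)
        ax.annotate(row["letter"], (row["centroid_x"], row["centroid_y"]),
                    fontsize=14, fontweight="bold", ha="center")
    lims = [xy.min(), xy.max()] if len(xy) else [0, 1]
    ax.plot(lims, lims, color="black", lw=0.8, ls="--")
    ax.set_xlabel("log2 signal, sample A")
    ax.set_ylabel("log2 signal, sample B")
    fig.tight_layout()
    fig.savefig(path, metadata=_figure_metadata(path))
    plt.close(fig)
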