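"""Region-set enrichment of bin clusters with stratified backgrounds.

For a chosen cluster, each annotation set (a BED file of intervals) yields
a 2x2 table — cluster/background vs overlapping/not — tested with a
two-sided Fisher's exact test. The universe is either all surviving bins
or only the genic (or intergenic) ones, so that annotations confined to
one compartment are not called enriched merely because the cluster lives
there too. A bin overlaps a set if any annotated interval covers >= 1 bp
of it (the same rule as blacklist removal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .core import BinGrid, GenomicInterval


@dataclass
class ContingencyTable:
    a: int   # cluster bins overlapping the annotation
    b: int   # cluster bins not overlapping
    c: int   # background bins overlapping
    d: int   # background bins not overlapping

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def universe(self) -> int:
        return self.a + self.b + self.c + self.d


def overlap_flags(grid: BinGrid,
                  regions: Sequence[GenomicInterval]) -> np.ndarray:
    """True per bin iff any region overlaps the bin by >= 1 bp."""
    return grid.overlap_bases(list(regions)) > 0


def odds_ratio(t: ContingencyTable) -> float:
    """Sample odds ratio; Haldane-Anscombe 0.5 correction when a cell is 0."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_cluster_enrichment(assign, letter: str,
                              annotation_sets: dict,
                              grid: BinGrid,
                              universe: str = "all",
                              cls=None) -> pd.DataFrame:
    """Fisher enrichment of one cluster against named annotation sets.

    ``annotation_sets`` maps set name -> list of intervals. ``universe``
    is ``all``, ``genic`` or ``intergenic``; the latter two need a
    :class:`~binsig.annotate.BinClassification` and restrict both cluster
    and background to that compartment. The exact p uses the uncorrected
    table; the Haldane-Anscombe correction applies to the reported odds
    ratio only. q is Benjamini-Hochberg across the sets tested in this
    call.
    """
    in_cluster = assign.mask(letter)
    if universe == "all":
        uni = np.ones(grid.n_bins, dtype=bool)
    elif universe in ("genic", "intergenic"):
        if cls is None:
            raise ValueError("stratified universe needs a bin classification")
        uni = cls.genic_mask if universe == "genic" else ~cls.genic_mask
    else:
        raise ValueError(f"unknown universe {universe!r}")
    in_cluster = in_cluster & uni
    if not in_cluster.any():
        raise ValueError(
            f"cluster {letter!r} has no bins within the {universe} universe"
        )
    background = uni & ~in_cluster
    rows = []
    for name, regions in annotation_sets.items():
        if len(regions) == 0:
            warnings.warn(f"annotation set {name!r} is empty; skipped")
            continue
        flags = overlap_flags(grid, regions)
        t = ContingencyTable(
            a=int((in_cluster & flags).sum()),
            b=int((in_cluster & ~flags).sum()),
            c=int((background & flags).sum()),
            d=int((background & ~flags).sum()),
        )
        _, p = fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
        orr = odds_ratio(t)
        rows.append({"set": name, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                     "odds_ratio": orr, "log2_or": float(np.log2(orr)),
                     "p": float(p)})
    if not rows:
        raise ValueError("no non-empty annotation sets to test")
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["direction"] = np.where(df["odds_ratio"] > 1, "enriched", "depleted")
    return df


def load_annotation_dir(directory) -> dict:
    """Directory of BED files -> {file stem: intervals}."""
    from .io import read_bed_intervals

    out = {}
    for path in sorted(Path(directory).glob("*.bed")):
        out[path.stem] = read_bed_intervals(path)
    if not out:
        raise ValueError(f"no .bed files found in {directory}")
    return out


def _stars(q: float) -> str:
    for cut, sym in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if q < cut:
            return sym
    return ""


def enrichment_plot(results: pd.DataFrame, path) -> None:
    """Horizontal bars of log2 odds ratio with significance stars on q."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .annotate import _figure_metadata

    if len(results) == 0:
        raise ValueError("no enrichment rows to plot")
    df = results.sort_values("log2_or")
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(df) + 1.5))
    colors = np.where(df["log2_or"] >= 0, "#d62728", "#1f77b4")
    ax.barh(df["set"], df["log2_or"], color=colors)
    span = max(1.0, df["log2_or"].abs().max())
    for y, (lor, q) in enumerate(zip(df["log2_or"], df["q"])):
        ax.text(lor + np.sign(lor or 1) * 0.03 * span, y, _stars(q),
                va="center", ha="left" if lor >= 0 else "right")
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("log2 odds ratio")
    fig.tight_layout()
    fig.savefig(path, metadata=_figure_metadata(path))
    plt.close(fig)
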