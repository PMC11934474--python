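"""Replicate consistency and global sample profiles.

PCA and correlation-based hierarchical clustering of samples over binned
log2 signal, plus per-bin replicate averaging. Both views answer the same
questions: do replicates of a condition group together, and does the
treatment separate samples genome-wide?
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .core import NormalizedTrack


@dataclass
class SignalMatrix:
    """bins x samples matrix of log2 normalized signal with sample metadata."""

    values: np.ndarray
    sample_ids: list
    conditions: list
    replicates: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a bins x samples matrix")
        if self.values.shape[1] != len(self.sample_ids):
            raise ValueError("column count does not match sample metadata")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal matrix contains non-finite values")

    @classmethod
    def from_tracks(cls, tracks) -> "SignalMatrix":
        return cls(
            values=np.column_stack([t.values for t in tracks]),
            sample_ids=[t.sample_id for t in tracks],
            conditions=[t.condition for t in tracks],
            replicates=[t.replicate for t in tracks],
        )


@dataclass
class PCAResult:
    coordinates: np.ndarray        # samples x components
    variance_explained: np.ndarray
    sample_ids: list

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"PC{i + 1}" for i in range(self.coordinates.shape[1])],
        )
        df.insert(0, "sample", self.sample_ids)
        return df


@dataclass
class CorrelationResult:
    matrix: np.ndarray             # samples x samples correlation
    linkage_matrix: np.ndarray     # scipy hierarchical merge encoding
    linkage_method: str
    correlation_method: str
    sample_ids: list


def pca_samples(m: SignalMatrix, n_components: int | None = None,
                center: bool = True, scale: bool = False,
                top_n_variable: int | None = None) -> PCAResult:
    """Project samples onto principal components of bin-feature space.

    Components carry a fixed sign convention (the loading with the largest
    magnitude is made positive) so results are reproducible bit-for-bit.
    """
    n_samples, n_bins = m.values.shape[1], m.values.shape[0]
    if n_samples < 2 or n_bins < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 bins")
    max_k = min(n_samples - 1, n_bins)
    if n_components is None:
        n_components = max_k
    if n_components > max_k:
        raise ValueError(
            f"cannot extract {n_components} components from "
            f"{n_samples} samples x {n_bins} bins"
        )
    x = m.values
    if top_n_variable is not None and top_n_variable < n_bins:
        order = np.argsort(x.var(axis=1))[::-1][:top_n_variable]
        x = x[np.sort(order)]
    x = x.T                                   # samples x features
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0)
        x = x / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    with np.errstate(invalid="ignore", divide="ignore"):
        coords = pca.fit_transform(x)
    # all-identical samples: zero total variance, report zero fractions
    variance_explained = np.nan_to_num(pca.explained_variance_ratio_,
                                       nan=0.0)
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(coords.shape[1]):
        load = pca.components_[k]
        j = int(np.argmax(np.abs(load)))
        if load[j] < 0:
            coords[:, k] = -coords[:, k]
    return PCAResult(coordinates=coords,
                     variance_explained=variance_explained,
                     sample_ids=list(m.sample_ids))


def correlation_cluster(m: SignalMatrix, method: str = "pearson",
                        linkage_method: str = "average") -> CorrelationResult:
    """Sample-sample correlation and hierarchical clustering on 1 - r."""
    if m.values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    sd = m.values.std(axis=0)
    if np.any(sd == 0):
        bad = m.sample_ids[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"sample {bad!r} has zero variance across bins")
    if method == "pearson":
        corr = np.corrcoef(m.values.T)
    elif method == "spearman":
        corr, _ = spearmanr(m.values)
        if np.isscalar(corr) or np.ndim(corr) == 0:  # exactly two samples
            r = float(corr)
            corr = np.array([[1.0, r], [r, 1.0]])
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    return CorrelationResult(matrix=corr, linkage_matrix=z,
                             linkage_method=linkage_method,
                             correlation_method=method,
                             sample_ids=list(m.sample_ids))


def merge_replicates(tracks, merged_id: str | None = None) -> NormalizedTrack:
    """Average signal per bin across replicate tracks of one condition.

    Averaging happens in the tracks' own space (all linear or all log2);
    mean-of-logs differs from log-of-means, so mixing spaces is an error.
    """
    if len(tracks) == 0:
        raise ValueError("need at least one track")
    first = tracks[0]
    spaces = {t.space for t in tracks}
    if len(spaces) > 1:
        raise ValueError(f"cannot merge tracks in mixed spaces: {spaces}")
    for t in tracks[1:]:
        if not t.grid.same_as(first.grid):
            raise ValueError(
                f"track {t.sample_id!r} is on a different grid"
            )
    mean = np.mean(np.column_stack([t.values for t in tracks]), axis=1)
    if merged_id is None:
        merged_id = "+".join(sorted(t.sample_id for t in tracks))
    return replace(first, sample_id=merged_id, values=mean,
                   source_ids=tuple(t.sample_id for t in tracks))
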