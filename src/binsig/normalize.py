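"""Normalization of raw binned counts.

Converts raw per-bin read counts into comparable signal:

* library-size (CPM) scaling — the default, and the recommended mode for
  broad histone marks undergoing global changes, where composition-aware
  factors can normalize genuine biology away;
* optional input-background correction (log2 ratio or floored subtraction);
* cross-sample factors: the median-ratio method (size factors dividing the
  raw counts) or trimmed-mean-of-M-values (TMM) composition factors that
  turn library sizes into effective library sizes;
* quantitative scaling by spike-in (exogenous-genome) read counts or by a
  mass-spectrometry genome-wide modification percentage;
* log2 transform with pseudocount.

Median-ratio and TMM assume most bins are unaffected between samples; when
a mutation removes a broad mark over much of the genome that assumption
fails, so these modes warn on use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import GridMismatchError, NormalizedTrack, TrackSet

log = logging.getLogger(__name__)

COMPOSITION_WARNING = (
    "median-ratio/TMM factors assume most bins are invariant; with global "
    "changes in broad histone marks they may reduce the statistical power "
    "to detect genuine biological changes"
)


@dataclass
class NormalizationFactors:
    """Per-sample factors produced by a normalization run."""

    sample_ids: list
    library_sizes: np.ndarray
    size_factors: np.ndarray | None = None        # median-ratio mode
    tmm_factors: np.ndarray | None = None         # TMM mode
    effective_library_sizes: np.ndarray | None = None
    scale_source: str = "none"                    # {none, chiprx, ms}
    scale_values: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample": self.sample_ids,
                           "library_size": self.library_sizes})
        if self.size_factors is not None:
            df["size_factor"] = self.size_factors
        if self.tmm_factors is not None:
            df["tmm_factor"] = self.tmm_factors
            df["effective_library_size"] = self.effective_library_sizes
        df["scale_source"] = self.scale_source
        df["scale_value"] = [self.scale_values.get(s, np.nan)
                             for s in self.sample_ids]
        return df


def library_size_normalize(ts: TrackSet,
                           effective_sizes: np.ndarray | None = None,
                           size_factors: np.ndarray | None = None,
                           ) -> list[NormalizedTrack]:
    """Counts-per-million over the grid's bins.

    ``value_ij = count_ij / N_j * 1e6`` with ``N_j`` the sample's total raw
    count over the grid, optionally replaced by TMM effective library sizes
    or combined with median-ratio size factors.
    """
    counts = ts.matrix()
    sizes = counts.sum(axis=0)
    if np.any(sizes <= 0):
        bad = ts.sample_ids[int(np.flatnonzero(sizes <= 0)[0])]
        raise ValueError(f"sample {bad!r} has zero library size")
    denom = sizes if effective_sizes is None else np.asarray(effective_sizes,
                                                             dtype=float)
    if size_factors is not None:
        denom = denom * np.asarray(size_factors, dtype=float)
    out = []
    for j, t in enumerate(ts.tracks):
        out.append(NormalizedTrack(
            sample_id=t.sample_id,
            values=counts[:, j] / denom[j] * 1e6,
            grid=ts.grid, space="linear",
            condition=t.condition, replicate=t.replicate,
        ))
    return out


def input_correct(chip: NormalizedTrack, input_track: NormalizedTrack,
                  mode: str = "ratio", pseudocount: float = 0.5,
                  ) -> NormalizedTrack:
    """Correct a depth-normalized ChIP track by its input control.

    ``ratio`` (default): log2((chip + c) / (input + c)), output in log2
    space. ``subtract``: max(chip - input, 0), output linear.
    """
    if not chip.grid.same_as(input_track.grid):
        raise GridMismatchError("ChIP and input tracks are on different grids")
    if chip.space != "linear" or input_track.space != "linear":
        raise ValueError("input correction expects linear-space tracks")
    if mode == "ratio":
        values = np.log2((chip.values + pseudocount)
                         / (input_track.values + pseudocount))
        space = "log2"
    elif mode == "subtract":
        values = np.maximum(chip.values - input_track.values, 0.0)
        space = "linear"
    else:
        raise ValueError(f"unknown input-correction mode {mode!r}")
    return NormalizedTrack(sample_id=chip.sample_id, values=values,
                           grid=chip.grid, space=space,
                           pseudocount=pseudocount if mode == "ratio" else 0.0,
                           condition=chip.condition, replicate=chip.replicate)


def median_ratio_factors(counts: np.ndarray, sample_ids=None,
                         ) -> NormalizationFactors:
    """Median-ratio size factors (bins x samples count matrix).

    For each sample j, the factor is the median over bins i (restricted to
    bins with all-positive counts) of ``count_ij / geomean_i`` where
    ``geomean_i`` is the geometric mean of bin i across samples. Normalized
    counts are ``count_ij / size_factor_j``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a bins x samples matrix with >= 2 samples")
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no bin has positive counts in every sample; filter low-count "
            "bins or use library-size normalization"
        )
    logs = np.log(counts[positive])
    log_geomeans = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_geomeans[:, None], axis=0))
    sample_ids = list(sample_ids) if sample_ids is not None else [
        f"s{j}" for j in range(counts.shape[1])]
    return NormalizationFactors(
        sample_ids=sample_ids,
        library_sizes=counts.sum(axis=0),
        size_factors=factors,
    )


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     n_obs: float, n_ref: float,
                     trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (edgeR's algorithm)."""
    both = (obs > 0) & (ref > 0)
    y_o, y_r = obs[both], ref[both]
    m = np.log2((y_o / n_obs) / (y_r / n_ref))
    a = 0.5 * np.log2((y_o / n_obs) * (y_r / n_ref))
    # delta-method variance of M; the weighted mean uses inverse variance
    v = (n_obs - y_o) / (n_obs * y_o) + (n_ref - y_r) / (n_ref * y_r)
    n = len(m)
    if n == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = ((rank_m >= lo_m) & (rank_m <= hi_m)
            & (rank_a >= lo_a) & (rank_a <= hi_a))
    if keep.sum() < 10:
        raise ValueError(
            "fewer than 10 bins survive TMM trimming; use median-ratio or "
            "library-size normalization"
        )
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(counts: np.ndarray, sample_ids=None,
                ref_sample: int | str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05,
                ) -> NormalizationFactors:
    """Trimmed-mean-of-M-values composition factors and effective library sizes.

    The reference sample (unless given) is the one whose 75th-percentile
    count fraction is closest to the mean of those fractions. For each other
    sample, log ratios M and average abundances A against the reference are
    computed over bins positive in both; the top and bottom ``trim_m`` by M
    and ``trim_a`` by A are discarded and the factor is ``2 ** (weighted
    mean of surviving M)`` with inverse-delta-method-variance weights.
    Factors are rescaled to geometric mean 1 and multiply the library sizes
    into effective library sizes.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a bins x samples matrix with >= 2 samples")
    n_samples = counts.shape[1]
    sample_ids = list(sample_ids) if sample_ids is not None else [
        f"s{j}" for j in range(n_samples)]
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    with np.errstate(invalid="ignore"):
        f75 = np.array([np.quantile(counts[:, j], 0.75) for j in
                        range(n_samples)]) / lib
    if ref_sample is None:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    elif isinstance(ref_sample, str):
        ref_idx = sample_ids.index(ref_sample)
    else:
        ref_idx = int(ref_sample)
    factors = np.ones(n_samples)
    for j in range(n_samples):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair_factor(counts[:, j], counts[:, ref_idx],
                                      lib[j], lib[ref_idx], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    log.warning(COMPOSITION_WARNING)
    return NormalizationFactors(
        sample_ids=sample_ids,
        library_sizes=lib,
        tmm_factors=factors,
        effective_library_sizes=lib * factors,
    )


def scale_quantitative(track: NormalizedTrack, method: str,
                       value: float) -> NormalizedTrack:
    """Quantitatively scale a depth-normalized linear track.

    ``ms``: multiply by (genome-wide modification percentage / 100).
    ``chiprx``: multiply by 1e6 / exogenous mapped reads (spike-in); the 1e6
    constant is arbitrary and cancels in between-sample ratios.
    """
    if track.space != "linear":
        raise ValueError("quantitative scaling expects a linear-space track")
    if value <= 0:
        raise ValueError(f"scale value must be positive, got {value}")
    if method == "ms":
        scaled = track.values * (value / 100.0)
    elif method == "chiprx":
        scaled = track.values * (1e6 / value)
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    return NormalizedTrack(sample_id=track.sample_id, values=scaled,
                           grid=track.grid, space="linear",
                           condition=track.condition,
                           replicate=track.replicate)


def log_transform(track: NormalizedTrack,
                  pseudocount: float = 1.0) -> NormalizedTrack:
    """log2(value + pseudocount); errors if the track is already log2."""
    if track.space == "log2":
        raise ValueError(
            f"track {track.sample_id!r} is already in log2 space"
        )
    return NormalizedTrack(
        sample_id=track.sample_id,
        values=np.log2(track.values + pseudocount),
        grid=track.grid, space="log2", pseudocount=pseudocount,
        condition=track.condition, replicate=track.replicate,
    )
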