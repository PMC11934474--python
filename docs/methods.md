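# Methods

`binsig` analyzes broad histone marks (H3K36me2, H3K27me3, H3K9me3,
H3K4me1, ...) from ChIP-Seq or CUT&RUN/TAG data without peak calling.
The genome is tiled into uniform windows ("bins", typically 10 kb), reads
are counted per bin upstream (e.g. with bedtools), and every downstream
question — how do two samples differ genome-wide, which bins behave
alike, which bins change significantly, what do the changed bins overlap —
is asked at the level of this fixed grid. This document records the models,
the defaults and why they were chosen, and the limits of what the synthetic
benchmark can show.

## Coordinate frame and input handling

All coordinates are BED-style: 0-based, half-open. A bin grid must be
sorted, non-overlapping, and uniform-width except for an optional
chromosome-end remainder bin. Counts are read from a configurable BED
column (default column 4). Bins overlapping a blacklist interval by ≥ 1 bp
are removed, as are bins whose raw count summed over all samples falls
below `min_total` (default 1, i.e. only bins empty in every sample).
Summing across samples — rather than requiring a minimum per sample —
deliberately keeps bins present in only one condition, which are exactly
the differential ones. Strand is ignored throughout: binned coverage is
unstranded.

Normalized tracks are written as bigWig. Values are stored by bigWig as
32-bit floats, so round trips are exact only to ~1e-4 relative; bigWig
output is linear-scale, with log transforms applied downstream (so that a
track is never logged twice, every track records its value space).

## Normalization

Library-size (counts-per-million over grid bins) is the default and the
recommended mode:

    value_ij = count_ij / N_j × 10^6,  N_j = Σ_i count_ij.

Two composition-aware alternatives are available behind the same surface:

* **median-ratio size factors** — for sample j, the factor is
  `exp(median_i(log count_ij − log geomean_i))` over bins with positive
  counts in every sample; raw counts are divided by the factor. This is
  the geometric (log-space) median, matching the reference implementation
  of the method; it coincides with the plain median of ratios whenever the
  median is a data point.
* **TMM** — trimmed mean of M-values against a reference sample (the one
  whose upper-quartile count fraction is closest to the mean of those).
  Per non-reference sample, log ratios M and abundances A are computed over
  bins positive in both samples, the top/bottom 30% by M and 5% by A are
  discarded (the canonical trims; configurable), and the factor is 2 to
  the inverse-variance-weighted mean of the surviving M values, with the
  delta-method variance `(N−y)/(Ny)` per sample as the (inverse) weight.
  Factors are rescaled to geometric mean 1 and multiply the library sizes
  into effective library sizes. The implementation agrees with
  edgeR::calcNormFactors to ~1e-7 on random matrices (checked by an
  Rscript oracle test).

Both alternatives assume that most bins are invariant. When a mutation
erases a broad mark over a substantial fraction of the genome — the very
situation binned analysis targets — that assumption fails and the factors
absorb genuine biology. The benchmark below quantifies this; the library
warns whenever the composition-aware modes are used.

Input (background) correction, for ChIP with an input control, defaults to
`log2((chip + 0.5)/(input + 0.5))` on depth-normalized linear tracks, with
a floored subtraction `max(chip − input, 0)` as the alternative. The
ratio form is the standard for ChIP-vs-input; the pseudocount of 0.5 CPM
bounds the ratio for empty bins.

Quantitative scaling accepts either a mass-spectrometry genome-wide
modification percentage (`value × pct/100`) or a spike-in (exogenous
genome) read count (`value × 10^6/exogenous_reads`). The 10^6 constant is
an arbitrary unit choice; it cancels in any between-sample ratio.

The default log transform is `log2(value + 1)` on the CPM scale.

## Cohort exploration

PCA and correlation-based hierarchical clustering operate on the bins ×
samples matrix of log2 signal (bins surviving the filters; optionally the
top-n most variable). PCA centers by default, does not scale, and fixes
component signs (largest-magnitude loading positive) so outputs are
bit-reproducible. Correlation distance is 1 − r (Pearson default,
Spearman available) with average linkage; ties in the dendrogram follow
sample order. Replicates merge by the per-bin arithmetic mean, in the
space of the inputs — mean-of-logs is not log-of-means, so mixing spaces
is an error; the default workflow merges linear tracks and logs afterward.

## Genic/intergenic annotation

The genic compartment is the union of gene intervals (BED, or GFF3/GTF
records of feature type `gene`), merged including book-ended neighbors;
intergenic is the complement. A bin is genic when at least half its bases
(configurable threshold) fall in the union, with the boundary case genic.
Majority overlap was chosen over any-overlap because at 10 kb resolution
any-overlap would label nearly every bin near a gene edge genic; the rule
is deterministic and symmetric. No genome assemblies are bundled — users
supply interval files.

## Bin clustering

Bins are clustered in the two-dimensional space of their (x, y) log2
signal in the two compared samples — the same coordinates as the
scatterplot — using HDBSCAN (scikit-learn implementation,
excess-of-mass cluster selection), with no standardization: both axes are
already on the same scale. Clustering sees no differential-binding
statistics; it groups bins purely by where they sit in signal space, so a
"depleted" cluster and an "unchanged" cluster emerge from density alone.
`min_cluster_size` sets the smallest allowed cluster; `min_samples` is
the conservativeness dial (larger → more points declared noise). Clusters
are lettered A, B, C, … by descending size, ties broken by ascending
centroid x then y — the letters are reproducible run to run, and more
than 26 clusters is reported as an error suggesting coarser parameters.
All bins are clustered (no subsampling); 50,000 points take a few seconds.

## Differential binding

Per-bin two-group differential binding uses a reproducibility-optimized
t-type statistic

    d_g = |x̄1_g − x̄2_g| / (α1 + α2 · s_g),

with s_g the pooled standard error. The (α1, α2) pair and a top-list size
k are not fixed a priori: they are selected to maximize

    Z_k(α) = (R_k(α) − R0_k(α)) / s_k(α),

where R_k is the mean fraction of the top-k bin lists shared by two
within-group bootstrap resamples (B pairs, default 100), s_k its bootstrap
standard deviation, and R0_k the same overlap under a null in which each
bin's values are permuted independently across samples. The per-bin
permutation destroys the group structure while preserving each bin's
marginal distribution (so heteroscedastic bins are equally heteroscedastic
in the null); permuting whole column labels instead would leave correlated
planted effects partially intact in the null and deflate Z. The candidate
grid is α1 ∈ {0, 0.01, 0.05, 0.1, 0.35, 0.7, 1.4, 2.8, 5}, α2 ∈ {0, 1}
(excluding the undefined (0, 0)), k quasi-geometric up to a quarter of the
bins; ties resolve toward smaller α1, then α2 = 1, then smaller k, making
the search deterministic for a fixed seed. α = (0, 1) recovers the
ordinary pooled |t|; (1, 0) recovers |Δmean| — both anchored by oracle
tests.

Significance is a permutation FDR: for each relabeling p of samples into
groups, null statistics d_p are computed with the selected α, and

    FDR(g) = mean_p #{d_p ≥ d_g} / #{d_obs ≥ d_g},

made monotone non-increasing in d and clipped to [0, 1]. When the number
of distinct relabelings is small (e.g. 3 vs 3 has 9 usable splits) they
are enumerated exactly instead of sampled. The observed labeling is
excluded from the null in both modes: including it would floor every FDR
at 1/#permutations (0.1 at 3 vs 3) and make calls at FDR < 0.05
structurally impossible. The reported "FDR" is therefore a q-value-like
permutation quantity, not a Benjamini–Hochberg adjustment of parametric
p-values.

Because the statistic is rank-based and distribution-free, it accepts
depth-normalized, spike-in-scaled or mass-spec-scaled log2 signal alike.
Each group needs ≥ 2 replicates; single-replicate designs are supported
only for the non-differential analyses (scatterplots, clustering). logFC
is mean(treated) − mean(control) in log2 units; bins with FDR below the
cutoff (default 0.05) are labeled `down`/`up` by its sign.

## Region-set enrichment

For a chosen cluster and each annotation set (a BED file; a directory of
them maps stem → set name), a 2×2 table — cluster/background ×
overlapping/not — is tested with a two-sided Fisher's exact test; a bin
"overlaps" a set when any interval covers ≥ 1 bp of it (the blacklist
rule). The universe is all surviving bins, or only the genic or only the
intergenic ones; stratification prevents an annotation that lives almost
entirely in one compartment from appearing enriched merely because the
cluster does too. The two-sided p covers enrichment and depletion in one
call, with the direction read off the odds ratio. Zero cells get the
Haldane–Anscombe 0.5 correction for the *reported* odds ratio only — the
exact p always uses the uncorrected table. q is Benjamini–Hochberg across
the sets tested in one invocation.

## Synthetic data and benchmark

The generator emulates binned broad-mark data on a toy multi-chromosome
genome: blocky genic architecture (geometric block lengths, mean 5 bins)
and blocky covered domains (mean 20 bins), negative-binomial counts with
bin-type means (covered 200, background 5 per 10 kb bin) and dispersion
0.1, and R replicates per group (default 3). The altered group is the
*same* baseline replicate draws with the counts of the selected target
bins (a fraction of covered intergenic or covered genic bins) thinned by
`Binomial(count, depletion_factor)` — the downsampling design, in which
the altered samples derive from the originals. Invariant bins therefore
carry identical counts in both groups, exactly as when a real dataset is
downsampled in silico and compared to itself; the same thinning operation
is exposed (`downsample_regions`) for users with real tracks. Defaults:
50,000 bins of 10 kb, genic fraction 0.4, covered fraction 0.6 (broad
marks blanket the majority of the genome), thinning factor 0.3 in 20% of
covered intergenic bins.

What the generator does *not* emulate: mappability and GC structure,
input/background gradients, fragment-length effects, replicate-specific
efficiency differences, and biological between-replicate variation in the
altered group beyond the shared baseline. Passing benchmarks here show
the pipeline recovers planted depletion under the downsampling design;
they do not certify performance on independently grown biological
replicates, where within-group variance is larger.

The benchmark pipeline restricts analysis to signal bins (raw mean ≥ 25
per sample, cleanly separating covered from background at the default
means), normalizes by library size and by TMM, runs the differential
analysis identically under both, and scores calls against the planted
truth: TP = depleted bin called down; FP = any significant call on an
invariant bin, or an up call on a depleted bin; FN = depleted bin not
called; TN = the rest. Precision, specificity, sensitivity (recall) and
F1 follow the usual definitions.

The normalization comparison is run under global depletion — every
covered intergenic bin thinned, i.e. half of all covered bins changed
(matching the regime that motivates the method, where ~50% of signal
bins lose the mark). In that regime the depleted bins dominate TMM's
trimmed mean, the factors absorb much of the true shift, and library-size
normalization recovers strictly more true positives while TMM additionally
produces spurious upregulated calls. With only a small fraction of bins
depleted the two modes perform near-identically — composition correction
is harmful exactly when changes are widespread and one-sided.

## Problem sizes and runtime

Defaults are sized for interactive use on one CPU: the 50,000-bin
planted-depletion run (bootstrap B = 100, 9 exact permutation splits)
takes ~20 s; the two-normalization benchmark ~40 s; `scripts/acceptance.py`
about a minute end to end. B = 500 and n_perm = 1000 are appropriate for
publication-grade runs and scale linearly.

## Known limitations

* Adjacent significant bins are not merged into regions; the intended
  workflow hands the exported BEDs to interval tools (e.g. bedtools merge).
* Two-group designs only; no covariates or batch terms.
* The FDR's resolution at 3 vs 3 replicates is limited by the 9 usable
  label splits; with many strong effects this is offset by the size of the
  observed tail, but FDRs for isolated weak effects are coarse.
* BAM processing (read counting into bins) is upstream of this package.
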