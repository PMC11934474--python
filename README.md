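# binsig

Reference-agnostic analysis of **broad histone marks** (H3K36me2, H3K27me3,
H3K9me3, H3K4me1, ...) from ChIP-Seq or CUT&RUN/TAG data, for researchers
whose signal of interest spreads over megabase-scale domains rather than
sharp peaks. Peak callers fragment diffuse domains into arbitrary pieces;
`binsig` instead divides the genome into uniform windows ("bins", e.g.
10 kb), and performs every comparison on that fixed, assumption-free grid:

* **normalize** binned counts — library size (CPM), median-ratio or TMM
  factors, input correction, and quantitative scaling by spike-in
  (ChIP-Rx) reads or mass-spectrometry modification percentages; bigWig
  output;
* **explore** cohorts — PCA, correlation-based hierarchical clustering,
  replicate merging;
* **annotate** bins genic/intergenic and build two-sample scatterplots;
* **cluster** bins by density (HDBSCAN) in the two-sample log-signal
  plane, independent of any differential statistics, lettered A–Z;
* **test** per-bin differential binding with a reproducibility-optimized
  t-type statistic: `d = |x̄₁ − x̄₂| / (α₁ + α₂·s)`, with (α₁, α₂) and the
  top-list size k chosen to maximize the bootstrap reproducibility
  Z = (R_k − R0_k)/s_k of top-ranked bins, and significance by
  permutation FDR — no distributional assumptions, so scaled counts are
  fine;
* **screen** clusters for enrichment/depletion in annotation region sets
  with Fisher's exact test against an all-bins or genic/intergenic-
  stratified background;
* **simulate** binned datasets with planted depletion (binomial
  downsampling) and benchmark any caller with precision / specificity /
  sensitivity / F1.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate an H3K36me2-like experiment — 5,000 bins of 10 kb, triplicates,
20% of covered intergenic bins thinned to 30% of their reads in the
"knockout" group — then run the full pipeline (filter → CPM → log2 →
optimize statistic → permutation FDR) and score it against the planted
truth:

```python
import binsig as bs

spec = bs.SimulationSpec(n_bins=5000, seed=11)
ts_wt, ts_ko, truth = bs.simulate_trackset(spec)
ts = bs.combine_groups(ts_wt, ts_ko)
design = bs.GroupDesign(ts_wt.sample_ids, ts_ko.sample_ids)

result, conf, mets = bs.run_pipeline(ts, design, truth)
print("selected statistic: a1=%.2f a2=%d k=%d Z=%.1f"
      % (result.a1, result.a2, result.k, result.z_score))
print("calls:", result.table["direction"].value_counts().to_dict())
print("confusion:", conf)
print("metrics:", {k: round(v, 3) for k, v in mets.items()})
```

prints

```
selected statistic: a1=0.70 a2=1 k=263 Z=7.5
calls: {'ns': 2399, 'down': 304}
confusion: ConfusionCounts(tp=304, fp=0, tn=2395, fn=4)
metrics: {'precision': 1.0, 'specificity': 1.0, 'sensitivity': 0.987, 'f1': 0.993}
```

The optimizer picked a stabilized statistic (α₁ = 0.7 damps the noisy
per-bin variance at n = 3), its top-263 list is reproducible across
bootstrap resamples 7.5 standard deviations beyond the null, and at
FDR < 0.05 the pipeline recovers 304 of the 308 planted bins with no
false positives and — on a dataset containing only depletion — zero
upregulated calls.

The same workflow is available from the shell, one subcommand per stage:

```bash
binsig normalize --beds wt_1.bed --beds wt_2.bed --beds ko_1.bed --beds ko_2.bed \
    --chrom-sizes hg38.sizes --mode library --out norm/
binsig scatter --bigwig-a norm/wt_1.bw --bigwig-b norm/ko_1.bw \
    --grid-bed norm/bins.bed --genes genes.bed --out scatter/
binsig cluster --scatter-tsv scatter/scatter.tsv --min-cluster-size 100 --out clusters/
binsig diff --bigwigs norm/wt_1.bw --bigwigs norm/wt_2.bw \
    --bigwigs norm/ko_1.bw --bigwigs norm/ko_2.bw \
    --grid-bed norm/bins.bed --groups 1,1,2,2 --out diff/
binsig enrich --clusters-bed clusters/clusters.bed --letter B \
    --annotations annotation_beds/ --universe intergenic --genes genes.bed --out enrich/
```

Every subcommand writes its resolved parameters next to its outputs and is
byte-reproducible for a fixed `--seed`.

## A note on normalization

Median-ratio and TMM factors assume most bins are unchanged. When a
mutation removes a broad mark across a large share of the genome — the
motivating use case — that assumption fails: the factors absorb the real
change, costing true positives and manufacturing false "upregulated"
bins. `binsig benchmark` demonstrates this on synthetic data (library-size
normalization recovers strictly more planted depleted bins than TMM under
global depletion), which is why library-size-only is the default and the
composition-aware modes warn on use.

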