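# Methods

This note records the models, parameter choices and numerical decisions
behind `somtopo`, and what the synthetic benchmarks do and do not show.

## Normalization

Size factors follow the median-of-ratios construction: the reference for
gene *g* is its geometric mean across samples, computed only over genes
with strictly positive counts in every sample (a zero anywhere removes
the gene from the reference but not from normalization); the factor for
sample *j* is the median over reference genes of `y_gj / geomean_g`,
taken in natural space (the median of the ratios themselves, not the
exponentiated median of log ratios — the two differ when the reference
gene count is even). Factors are rescaled to geometric mean 1 so that
log2 values are invariant to global sequencing depth. If no gene is
positive everywhere the factors are undefined and the call fails rather
than guessing.

Expression values are `log2(count / factor + 1)`. The +1 pseudocount
keeps zeros finite and makes the selection threshold interpretable: 12
log2 corresponds to ~4095 normalized reads.

## The self-organizing map

Training operates on the replicate-level normalized log2 columns — not
condition means — so within-condition variance can still influence the
layout; condition means are computed downstream as node statistics.
No feature standardization is applied: all columns are already on a
common log2 scale.

* **Grid.** `map_units = round(n_genes / target)` with target 35 genes
  per node, factored `rows x cols` with `|rows − cols|` minimal and
  rows ≥ cols (320 → 20×16, 100 → 10×10; a prime count degenerates to a
  single column with a warning). Nodes sit on an offset hexagonal
  lattice (odd rows shifted +0.5 in x, rows √3/2 apart), so every
  interior node has six neighbors at unit distance. Node IDs are
  1-based row-major; grid coordinates are 0-based.
* **Initialization.** Codebook rows are sampled uniformly without
  replacement from the data rows with the seeded generator. Random
  initialization is used deliberately; since one master map carries all
  overlay layers, relative arrangement is all that matters.
* **Schedule.** `total_steps = 100 × map_units` single-profile
  presentations (the iteration unit is a presentation, not an epoch;
  the alternative reading is exposed via `total_steps`). Presentations
  follow a fresh seeded shuffle each epoch. Learning rate decays
  linearly 0.05 → 0.01. The neighborhood is a bubble: all units within
  lattice distance r(t) of the BMU move by α(t)(x − w), with r(t)
  decaying linearly from the ⅔ quantile of all inter-unit distances to
  0, so only the BMU is updated at the end.
* **Assignment.** After training each gene is assigned to its BMU;
  distance ties break to the lowest node ID so runs are reproducible
  bit-for-bit. Empty nodes are legitimate (they carry missing values in
  topographies, rendered grey, never zero).

Quantization error (mean Euclidean distance to the BMU prototype) is
the convergence diagnostic; on the default synthetic dataset training
reduces it from ~1.7 (sampled-row initialization) to ~1.45.

## Topographies and selection

Node statistics pool genes × replicate samples (identical to the mean
of per-gene means when replicate counts are balanced, and simpler when
they are not). The high-transcription mask is strict (`mean > 12`); a
node at exactly the threshold is not selected. The 12-log2 default is
checked by `threshold_percentile`, which reports where the cutoff falls
in the distribution of gene-level global means (~75th percentile under
the default generator).

Substrate-specific nodes are high on the test substrate and high on
*no* control substrate (defaults: maltose and the cellulose control);
common nodes are the intersection of the substrate-specific sets.
Member genes are then filtered by `log2FC > 1` and `adjusted p < 0.05`
(both strict) against the reference substrate (maltose), either from
the built-in test or from an externally supplied DE table.

Secretion overlays count distinct proteins per node by default
(detected in at least one condition); `summed` counts every
(protein, condition) detection event. Hotspot selection takes the k
highest-count nodes with ties at the kth rank included — asking for the
top three can legitimately return four nodes when two tie, which is the
behavior the tie rule is designed to reproduce. Proteins whose gene is
absent from the model are reported, never silently dropped.

## Differential expression

A deliberately small NB test, not a GLM pipeline (an external DE table
is accepted as first-class input and preferred when available). Scaled
counts are modeled as NB with variance μ + φμ²; log2 fold changes use a
0.5 offset on both means; significance is a delta-method Wald test.

Dispersion handling is the one place where replication drives design.
A per-gene moment estimate at 3 vs 3 is so noisy that the Wald statistic
must be referred to a Student-t with n₁+n₂−2 df to stay calibrated
(the normal reference yields ~12% type-I error at nominal 5%), and that
heavy-tailed reference bounds attainable p-values away from zero
(at φ = 0.05 the statistic saturates near 7.6, p ≈ 1.6·10⁻³), costing
most of the BH-adjusted power. `de_table` therefore defaults to one
dispersion pooled across the entire gene set within conditions — the
information-sharing idea count-GLM tools implement with shrinkage —
under which the variance is well determined, the normal reference holds
the null at ~5–7%, and planted four-fold changes are recovered
essentially completely. `dispersion="per-gene"` restores the gene-wise
fit with its t reference. The pooled default assumes dispersion is
roughly common across genes; strongly gene-specific overdispersion
would make it anti-conservative for the noisiest genes, one reason the
external-table route exists. "FDR and Bonferroni" is resolved as:
Benjamini–Hochberg by default, Bonferroni available, with the method
recorded in the table metadata.

## NB-EM clustering baseline

The comparison baseline clusters genes on condition-effect patterns
under `y_gj ~ NB(s_j·exp(b_g + t_{k,c(j)}), φ)` with the per-gene
baseline b_g profiled out at its Poisson maximum (fitted totals equal
observed totals) and the cluster effect vectors t_k centered to mean
zero; φ is shared across genes for stability at small n. Profiling the
baseline is the point, not a convenience: it makes the clustering
insensitive to absolute transcription level, which is exactly the
property being compared against the SOM.

The fit is a generalized EM: responsibilities in the E-step; mixing
weights, two fixed-point passes on the effect vectors (Poisson-profile
updates, clipped to ±30 on the natural-log scale), and a
responsibility-weighted moment update of φ in the M-step. Because the
effect and dispersion updates are approximate, every proposal is
checked against the observed log-likelihood and rejected (terminating
the fit) if it would decrease it by more than 1e-10 — the reported
trace is monotone by construction, and in practice proposals are
accepted until convergence (Δlog-likelihood < 1e-6, max 200
iterations). Initialization seeds the k effect vectors from k distinct
genes drawn with the seeded generator; `k = n_genes` degenerates to one
gene per cluster with a warning.

Clustering quality is Spearman's ρ (average ranks for ties) between
cluster-level global mean transcription and cluster-level secreted
protein counts, with the large-sample t approximation for p; an exact
permutation p is available for ≤ 10 clusters. Constant vectors leave ρ
undefined (NaN), not zero.

## Synthetic data

The generator emulates a five-substrate, three-replicate fungal
experiment at 3,500 genes. Ten planted groups cover the observed
transcriptional roles: constitutively high "housekeeping" genes, one
specifically induced group per substrate, a cellulose + biomass
co-induced group, a biomass-only group, and flat/low background. Counts
are NB with dispersion 0.05 around `L_j · 2^(baseline + effect)`, with
lognormal library factors (σ = 0.2).

Two calibrations are deliberate. First, groups are *coherent*: each
carries a fixed baseline offset around the genome center (8 log2) and
genes scatter around it with σ = 0.5, so group separation (+5 log2
induction) is ~8× the within-group noise — the regime in which a
topographic map can be expected to co-locate a group, and the
"planted node-level patterns" the benchmarks measure recovery of.
Per-gene baselines with genome-scale spread would smear every group
along an abundance gradient and make recovery metrics measure the
baseline distribution rather than the clustering. Second, the offsets
and group fractions place the 12-log2 threshold at the ~74th percentile
of gene-level global means, matching where the selection rule is meant
to operate.

Secretion: 10% of genes encode secreted proteins; each is detected per
condition with probability `logistic(−12 + 1.0 × planted condition
mean)`, so detection frequency rises steeply across the 10–14 log2
range. Annotations give CAZy-style family labels to most (not all)
secreted genes of the induced groups, leaving some predicted-secreted
genes function-unknown as in real annotation. An optional
`drop_substrate` reproduces the realistic failure mode of one condition
being unanalyzable.

What passing these benchmarks does *not* show: real data have
continuous abundance variation within co-regulated modules, partial
induction, and protein detection driven by abundance in the medium
rather than transcription alone. The synthetic results demonstrate the
machinery is correct and well calibrated under its stated model, not
that any particular ρ will be attained on real data.

### Recovery metrics and an honest geometric limit

`truth_metrics` reports node purity (size-weighted majority-group
fraction) and same-group pair recall at lattice adjacency ≤ 1. Purity
on the default dataset is ~0.98. Pair recall, however, is bounded by
map geometry: the SOM equalizes node occupancy near the 35-gene target,
so a group of m genes necessarily occupies ~m/35 nodes, and for a
compact blob of ~10 hexagonal cells the same-or-adjacent pair fraction
tops out near 0.5–0.6 regardless of how cleanly the group is separated.
With the default ten groups of 210–700 genes on a 100-node map the
measured recall is ~0.52; recall ≳ 0.9 requires groups small enough to
fit in ≤ 3 adjacent nodes (≤ ~105 genes at this target), as exercised
by the dedicated topographic-property test (8 × 40 genes on 16 units,
recall 1.0).

## Problem sizes

Default benchmark sizes are chosen to exercise the full workflow at
desk scale: 3,500 genes × 15 samples, 100 map units (10,000 training
presentations), NB-EM at k = 100, DE simulations at 2,000 genes ×
3 vs 3, and two-cluster EM recovery at 500 genes. The complete
pipeline, including the EM baseline, runs in well under a minute on one
CPU; the full test suite in about one to two minutes.

## Determinism

Every stochastic component (generator, codebook initialization,
presentation order, EM initialization, simulations) draws from
`numpy.random.default_rng` seeded explicitly; ties break by lowest
index; outputs are written with fixed formatting. Identical inputs and
seeds reproduce every output file byte for byte.
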