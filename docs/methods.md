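# Methods

This note documents the models, parameter choices and numerical conventions
behind `coexnet`, in the order the pipeline runs them.

## Depth normalisation

Raw count libraries are downsampled to a fixed depth *d* (default 10 M
reads) *k* = 5 times, and expression is the per-cell **median TPM** across
the draws. Sampling is without replacement — each library column is a
multivariate hypergeometric draw over genes — which is the exact model of
selecting a subset of the physical reads; a with-replacement multinomial
mode (`with_replacement=True`) is offered for speed and is statistically
indistinguishable when *d* is small relative to the library. With an even
number of draws the median is the mean of the two central order statistics.
Counts are converted to TPM as `1e6 · (count/length) / Σ(count/length)` per
library, so only relative transcript lengths matter and every non-empty
column sums to exactly 1e6.

## Zipf QC

For each library, genes with TPM ≥ 1 are ranked in descending abundance and
an OLS line is fitted to (log₁₀ rank, log₁₀ TPM). The TPM ≥ 1 floor keeps
near-zero noise out of the log fit. A library is *compliant* when the slope
lies in [−1.5, −0.5] and R² ≥ 0.8 — a pragmatic gate around the ideal
Zipf slope of −1, wide enough for real library-preparation variation.
Dispersion statistics use the sample SD (ddof = 1) by default; `ddof=0`
switches to the population convention. CoV is undefined (flagged NaN, not
an error) for genes with zero mean.

## Detection filtering

A gene is retained when its TPM is ≥ `min_tpm` (default 10) in at least
`min_samples` (default 1) libraries; both comparisons are inclusive, so a
gene sitting exactly on the threshold is kept. The detection summary counts
genes detected in at least ⌈f·n⌉ libraries (default f = 0.9; a flag
switches to floor, since the rounding convention at fractional sample
counts is genuinely ambiguous) and genes with median TPM **strictly** above
the threshold. Top-N selection ranks genes by summed abundance with a
lexicographic tie-break for determinism.

## Correlation

Correlations are computed on raw TPM, not log TPM: threshold-graph
analyses of TPM compendia conventionally feed the untransformed values, and
a `log2p1` flag exists for sensitivity analysis. Spearman is Pearson on
average-ranked profiles (ties get mean ranks). Zero-variance profiles have
no defined correlation; they are flagged degenerate, their rows/columns set
to 0, and excluded from graphs. The gene×gene matrix is computed in row
blocks over a single standardised (centred, L2-normalised) copy of the
data; block results agree with the whole-matrix product to below 1e-10
regardless of block size, and the final matrix is symmetrised exactly and
clipped to [−1, 1]. Symmetry, range and unit diagonal are asserted on every
construction.

## Threshold graphs

Edges are kept when *r* ≥ threshold (inclusive ≥, matching the convention
of reporting "correlations of ≥ t"); entities with no retained edge are
dropped, so node counts can fall below the entity count. The scan table is
computed from one sorted pass over edge values and per-entity maxima —
a node is present at *t* iff its maximum off-diagonal *r* ≥ *t* — and is
contract-tested against per-threshold rebuilds. The maximum full-inclusion
threshold is the minimum over entities of their maximum off-diagonal
correlation, floored to a 0.01 grid (all published values of this kind are
printed to two decimals). No automatic "optimal elbow" is chosen from the
scan: that choice is left to the user, with the scan table as evidence.

## Markov clustering

MCL iterates on the column-stochastic matrix of the weighted adjacency plus
self-loops (weight 1, the standard regularisation that guarantees
aperiodicity): expansion = matrix power 2, inflation = elementwise power
(default 1.7) followed by column renormalisation. The sparse backend prunes
entries below 1e-5 per iteration and renormalises — necessary for
10k-node graphs — and is contract-tested to produce identical partitions
to the unpruned dense iteration on small random graphs. Convergence is
declared when the max elementwise change drops below 1e-8; hitting the
iteration cap (100) returns the current clustering with `converged=False`
and a warning rather than failing. Clusters are read from the non-zero
pattern of the converged matrix: nodes with self-flow are attractors,
attractors sharing basin members form one attractor system, and each node
joins the system(s) it flows into. A node attracted to several systems is
assigned to the larger cluster (ties: lower cluster number) and the event
logged; nodes with no attractor flow (not observed under defaults) go to
`unassigned`. Clusters are numbered 1..K by decreasing size, ties broken by
smallest member id, and provably never span connected components of the
input graph. The whole procedure is deterministic. MCL runs on edge
weights by default; `use_weights=False` binarises, as the effect of weight
use on cluster boundaries is a legitimate sensitivity axis.

## Profiles, enrichment, marker screen

Cluster profiles are unweighted arithmetic means of member TPM per sample.
Enrichment uses the one-sided hypergeometric upper tail P(X ≥ k) with the
**detection-filtered gene list as the universe** — the matrix actually
clustered — and Benjamini–Hochberg correction jointly across all
cluster×set pairs. The group-ratio screen compares group means with a
pseudocount ε = 1 TPM: ratio = (mean_A + ε)/(mean_B + ε). The reciprocal
identity ratio(A,B)·ratio(B,A) = 1 holds to one ulp (floating-point
division); a reference-gene mode flags genes enriched at least as strongly
as a chosen marker (e.g. *Fcgr1* for macrophage-vs-DC screens).

## Synthetic data generator

The generator emulates the data properties the analysis assumes, with full
ground truth:

- **Baseline abundance**: gene *g* gets `rank^(−a)` (Zipf exponent
  *a* = 1.0 by default) over a random rank permutation, scaled to sum to
  1e6 TPM.
- **Planted modules**: member genes are jointly multiplied by a fold-change
  (default 8×) in active samples. Three kinds: *signal* modules active in
  declared sample groups; an *IEG* artifact module active in a random 50%
  of samples regardless of group (dissociation-stress mimic); *contaminant*
  modules active only in libraries of one project/batch. Default conditions:
  2,000 genes, 8 groups × 4 replicates (6 mononuclear-phagocyte, 2 DC
  groups across 4 projects), six 40-gene signal modules, a 24-gene IEG
  module and a 16-gene contaminant module. The default contaminant project
  spans two groups whose signal modules are each single-group, so batch
  contamination is statistically distinguishable from biology.
- **Noise**: observed TPM = mean · exp(N(0, σ)), σ = 0.4 for ordinary
  genes and 0.1 for the housekeeping fraction (5% of genes), then each
  library renormalised to 1e6. Renormalisation preserves within-module
  proportionality, so noiseless module members correlate at exactly 1.
- **Counts**: effective lengths log-uniform in [500, 5000] nt; per-library
  read totals drawn uniformly in [depth, 2·depth] (default depth 10 M) and
  allocated multinomially over length-weighted TPM shares. Heterogeneous
  totals are deliberate: they give the downsample-to-fixed-depth stage real
  work, as when normalising mixed-depth public libraries; `depth_spread=1`
  makes totals exactly `library_depth`.
- **Seeding**: one root seed; every purpose (rank permutation, membership,
  noise, lengths, depths, counts, each module's activity) draws from its
  own `SeedSequence` child with a fixed spawn key, and module membership
  comes from disjoint chunks of a single permutation. Adding a module
  therefore never perturbs earlier modules' membership or the noise field,
  and identical specs give bit-identical output.

Effect size (8×), IEG prevalence (50%) and noise SD (0.4) are calibration
choices representative of strong tissue-restricted expression programmes,
not estimates of any particular data set. What passing tests show is that
the pipeline's machinery is correct and that clearly-structured modules are
recovered; real atlases add between-study batch structure, unbalanced group
sizes, and overlapping module membership that the generator intentionally
omits (module gene sets here are disjoint by construction).

## Problem sizes and tolerances

The test suite and acceptance script run at the default synthetic
conditions (2,000 genes × 32 libraries; 5,000 genes for the Zipf-recovery
check; ≤100-node graphs for the MCL dense-reference comparison; 200
repeated draws for downsampling moments; 1,000 permutations for enrichment
calibration) — sizes chosen so the full validation completes in seconds
while leaving every statistical check well-powered. Key tolerances:
blockwise-vs-direct correlation 1e-10; planted-module recovery ARI ≥ 0.9
across seeds; Zipf slope within ±0.15 of the generating exponent at 5,000
genes (the log-normal noise re-orders ranks and steepens the fitted slope
by ≈0.08 at σ = 0.4, which the band accommodates); downsampling mean within
3 SE of the hypergeometric expectation; enrichment type-I ≤ 0.06 at
α = 0.05 (the discrete hypergeometric tail is conservative, so the
empirical rate sits below the nominal level).

## Known limitations

- Gene-level TPM is taken as given; transcript-to-gene aggregation and
  pseudoalignment are upstream concerns.
- No batch-effect modelling or correction: the pipeline exposes batch
  structure (project-restricted clusters, sample-network layout) but does
  not remove it.
- MCL cluster boundaries depend on implementation details (self-loop
  weight, pruning); validation is therefore property-based (partition
  invariants, dense-reference agreement, planted recovery), not equality
  with any third-party MCL build's output.
- The scan table deliberately stops short of automatic threshold selection.
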