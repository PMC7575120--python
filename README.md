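# coexnet

Correlation-network meta-analysis of bulk RNA-seq expression atlases.

When hundreds of RNA-seq libraries from many studies profile related cell
populations — for example monocytes, tissue macrophages and dendritic cells
isolated from different mouse tissues — the structure of the data can be read
from two graphs: a **sample-to-sample network**, in which libraries are nodes
and edges connect libraries whose genome-wide TPM profiles correlate above a
threshold, and a **gene co-expression network (GCN)**, in which genes are
nodes and edges connect transcripts whose expression profiles across all
libraries correlate above a threshold. Clustering the GCN yields coherent
modules: generic lineage programmes, tissue-specific signatures, cell-cycle
genes, dissociation-induced immediate-early-gene artifacts, and
batch-restricted contamination. `coexnet` packages that workflow as a tested
library and CLI, for computational biologists integrating heterogeneous bulk
(or pseudo-bulk) RNA-seq compendia.

## The method

1. **Depth normalisation.** Each library of raw counts is downsampled
   without replacement (multivariate hypergeometric) to a fixed depth
   (default 10 M reads), five times; expression is the median TPM across the
   draws. This removes depth as a between-study variable.
2. **QC.** Each library's rank-abundance distribution is checked against
   Zipf's law: on log–log axes, TPM against rank should be near-linear with
   slope ≈ −1. Per-gene dispersion (mean, SD, CoV = SD/mean) summarises
   variability across the atlas.
3. **Detection filtering.** Transcripts never reaching 10 TPM in any library
   are removed before network construction.
4. **Correlation networks.** All-pairs Pearson (or Spearman) correlation *r*
   between samples and, inversely, between genes; computed blockwise so an
   18k-gene matrix fits in memory. A threshold graph keeps edges with
   *r* ≥ the cutoff (inclusive) and drops isolated entities. A scan table of
   (threshold, nodes, edges) supports choosing the cutoff, and the *maximum
   full-inclusion threshold* is the largest grid value at which every entity
   still has an edge.
5. **Markov clustering (MCL).** The GCN is clustered by alternately
   expanding (matrix power) and inflating (elementwise power, default
   inflation 1.7) a column-stochastic flow matrix until convergence;
   basins of attraction are the clusters, numbered by decreasing size.
   Implemented from scratch with a pruned sparse backend and an exact dense
   reference backend.
6. **Profiling.** Cluster average-expression profiles; hypergeometric
   gene-set enrichment (GMT input, Benjamini–Hochberg corrected); and an
   averaged-expression group-ratio screen, e.g. macrophage-vs-DC marker
   discovery relative to a reference gene.

A fully ground-truthed **synthetic-data generator** emulates the statistical
structure this analysis assumes — Zipf-like abundance, planted co-expression
modules, housekeeping genes, an immediate-early-gene artifact module,
batch-restricted contamination, and the count/downsampling layer — so every
stage is testable offline.

## Worked example

```python
from coexnet import *
from coexnet.synthetic import SyntheticSpec
from coexnet.pipeline import recovery_ari

tpm, counts, annotation, truth = generate_expression(SyntheticSpec(), seed=1)
fit = fit_power_law(tpm.values[:, 0])
filtered = filter_detected(tpm, min_tpm=10.0, min_samples=1)
sample_corr = correlation_matrix(filtered, axis="samples")
gene_corr = correlation_matrix(filtered, axis="genes")
g = build_threshold_graph(gene_corr, 0.75)
clusters = run_mcl(g, MclParams(inflation=1.7))
```

printing, step by step:

```text
atlas: 2000 genes x 32 libraries
library 1 rank-abundance slope: -1.106 (R^2 0.987)
detection filter (>=10 TPM in >=1 library): 2000 genes kept
max sample-network threshold including all libraries: r >= 0.88
gene network at r >= 0.75: 446 nodes, 4393 edges
MCL (inflation 1.7): 51 clusters, largest: [80, 41, 41, 41, 41, 40]
recovery of planted modules, ARI = 0.994
```

The slope near −1 confirms Zipf-like abundance; the gene network at
*r* ≥ 0.75 isolates the co-expressed genes from the uncorrelated background
(446 of 2000 genes have at least one strong edge); the six planted 40-gene
modules emerge as the largest clusters (the 80-gene cluster joins the two
liver/spleen groups' shared module with correlated partners; trailing
clusters are small background fragments); and the adjusted Rand index of
0.994 against the generator's truth labels shows the pipeline recovers the
planted structure almost perfectly at noise SD 0.4.

The same stages run from the shell:

```sh
coexnet simulate --seed 1 --outdir sim/
coexnet filter sim/tpm.tsv --out filtered.tsv --summary-out summary.json
coexnet network filtered.tsv --axis genes --r-min 0.75 --out edges.tsv
coexnet cluster edges.tsv --inflation 1.7 --out clusters.tsv
coexnet run config.yaml          # whole pipeline from a YAML config
```

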