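# graftstates

Transcriptomic analysis of **injured tubular epithelial cell states in
kidney allografts**: how to define highly specific marker gene sets for
an injured cell state from snRNA-seq, quantify how close leukocytes sit
to those cells in spatial data, score bulk transplant biopsies against
the marker sets, and ask whether the resulting injury score stratifies
graft survival.

The package is aimed at computational biologists working on transplant
rejection (T-cell-mediated rejection, TCMR, and related diagnoses) or,
more generally, on rare-cell-state signatures that must transfer from
single-cell discovery data to bulk clinical cohorts.

## What it computes

**Marker selection for a target injury population (TP).**  Candidate
markers are genes upregulated in the TP versus all other cells
(two-sided Wilcoxon rank-sum on log-normalized expression, BH-adjusted
p < 0.05, |log2FC| > 1, expressed in ≥ 10% of the up-group's cells).
Candidates must then (i) have strictly higher mean expression in the TP
than in the *adjacent* injury state of the same cell type, and (ii)
satisfy a neighborhood specificity rule: with k-cell neighborhoods of
nearest neighbors (k = 100, PCA space) built around every cell outside
the TP and neighborhoods overlapping the TP discarded, the TP mean must
exceed 1.25 × the largest neighborhood mean.  The result is a marker
set whose expression is demonstrably concentrated in the TP rather than
diffused over the rest of the expression manifold.

**Gene-set scoring of bulk cohorts.**  A biopsy's score for a marker
set is the log2 geometric mean of the set's genes, normalized so the
mean score over nephrectomy control biopsies is exactly 0:

    score(s) = mean_g log2 x[g, s] − mean_{c ∈ controls} mean_g log2 x[g, c]

Scores read as log2-fold signature expression versus non-rejecting
tissue.  Cohorts are stratified at the median score of the full
population, and above- vs below-median graft survival is compared
within a diagnosis by Kaplan–Meier / log-rank with administrative
censoring at 36 months and BH-adjusted fdr across gene sets.

**Spatial direct-neighbor co-occurrence.**  For segmented-cell tables
(centroids in µm), the co-occurrence ratio of query type B around
anchor type A at distance d is the fraction of B among all cells lying
within ≤ d of an anchor, divided by B's marginal fraction; cells within
25 µm count as direct neighbors.  Enrichment/depletion across samples
is tested with a two-sided one-sample t-test of per-sample ratios
against 1, BH-corrected across type pairs.

**Composition and concordance statistics.**  Two-group comparisons of
cell-type proportions (Student's t, and arcsine-square-root transformed
empirical-Bayes moderated t for deconvolution-style estimates), and
Spearman correlation of log2 fold-changes over the top increased and
decreased genes to measure cross-dataset conservation of an expression
response.

**Synthetic data with planted truth.**  Negative-binomial snRNA-seq
cohorts with planted marker genes, spatial point patterns whose
direct-neighbor ratio is calibrated to a chosen ρ, and bulk cohorts
whose graft-loss hazard is log-linear in latent injury scores — so
every pipeline stage can be validated against ground truth.

## Worked example

`examples/` contains one narrative script per capability.  Running
`python examples/01_markers_from_snrnaseq.py` prints:

```
cells: 5000, genes: 2000
selected markers: 20
planted exclusive markers recovered: 20/20
false positives: 0

top of the audit trail (TP mean vs worst neighborhood):
          tp_mean  adjacent_mean  max_neighborhood_mean  ratio
gene
gene0015   20.745          4.797                  6.404  3.240
gene0017   42.076          9.885                 13.357  3.150
gene0012   61.017         15.722                 19.494  3.130
gene0001   46.033         12.305                 14.896  3.090
gene0009   28.277          7.836                  9.781  2.891
```

All 20 markers planted exclusively in the target injury state are
recovered with no false positives; the audit shows each gene's mean in
the target population, in the adjacent injury state, and in the worst
(highest) 100-cell neighborhood outside the target — the `ratio` column
is the specificity margin over that worst neighborhood.  Five genes
planted in *both* injury states were correctly rejected.

`examples/02_spatial_proximity.py` recovers a planted 2× macrophage
enrichment around injured cells (mean 25-µm ratio 2.006 over five
sections, BH-adjusted p < 1e-4) while healthy tubule sits at ratio 1.00;
`examples/03_bulk_scoring_survival.py` shows control scores averaging
exactly 0, elevated scores in TCMR/Mixed biopsies, the median-split
survival test, and score persistence in patients whose follow-up
biopsies return to no-rejection; `examples/04_composition_and_concordance.py`
detects a planted leukocyte expansion and measures ρ ≈ 0.93 log2FC
concordance between independently simulated cohorts.

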