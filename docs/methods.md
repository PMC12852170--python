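# Methods

This note documents the models, conventions and numerical choices
behind `graftstates`, in the order the pipeline runs.

## Normalization and differential expression

Counts are depth-normalized and log-transformed as
`ln(1 + scale · count / total)` with `scale = 10,000` (the common
single-cell convention; no authoritative scale factor exists for this
kind of analysis, so the default is documented rather than inferred).
Sparse zeros are preserved exactly.

The DE statistic is the two-sided Wilcoxon rank-sum test on normalized
values.  Two regimes:

* **Exact**: when the smaller group has ≤ 8 cells *and* the number of
  group assignments C(n, min) is ≤ 20,000, the null distribution of the
  rank sum is enumerated completely, respecting the observed tie
  structure.  The cap keeps the exact path where it is both feasible
  and where the normal approximation is weakest (tiny groups).
* **Asymptotic**: otherwise, a tie-corrected normal approximation
  without continuity correction.  Omitting the correction keeps the
  p-value exactly symmetric under group exchange; at the group sizes
  where the asymptotic path is active its effect is negligible.

Effect size is `log2((mean expm1(A) + 1) / (mean expm1(B) + 1))` — the
log2 ratio of back-transformed group means with pseudocount 1.  The
referenced single-cell toolchains changed this convention across
versions; this variant is fixed and used consistently everywhere a mean
of expression is needed (DE, adjacent filter, neighborhood means).

Significance filtering defaults to |log2FC| > 1, BH-adjusted p < 0.05,
and expression in ≥ 10% of cells of the *upregulated* group (group A
for up-genes, group B for down-genes); the fraction selector can be
pinned to either group.  The BH family is always the set of genes
tested in one call (one cell type × one contrast).

## Marker selection

The four steps and their free parameters:

1. **Candidates** — DE of the target population (TP) against all other
   cells, retaining upregulated genes under the standard filters.  The
   candidate step reuses the group-DE thresholds; nothing suggests a
   different setting, and the downstream filters dominate specificity.
2. **Adjacent filter** — keep genes with strictly greater TP mean than
   the adjacent injury state's mean (ties drop; the strict rule is the
   conservative reading).
3. **Neighborhoods** — around every cell *not* in the TP, its k = 100
   nearest cells (seed included, so a neighborhood has exactly k
   members) in a 30-component PCA of the log-normalized matrix,
   Euclidean metric.  kNN ties break by ascending cell index, and the
   PCA uses a fixed-seed randomized SVD, so the construction is fully
   deterministic.  Neighborhoods containing any TP cell are discarded.
   The embedding choice is the major interpretive decision here:
   dissociated nuclei have no spatial coordinates, so "nearest
   neighbors" can only mean expression space, and PCA-Euclidean is the
   standard operationalization.
4. **Specificity** — keep a gene iff its TP mean exceeds
   `fold_threshold` (default 1.25) × the **maximum** retained-
   neighborhood mean.  Comparing against the maximum is the strictest
   reading of "greater than every other neighborhood"; a mean-of-means
   variant is available (`neighborhood_reference="mean"`).

The output is ordered by the TP-mean / worst-neighborhood-mean ratio,
with the full audit (TP mean, adjacent mean, worst neighborhood mean,
ratio) attached.  Raising the fold threshold can only shrink the set.

## Gene-set scoring of bulk cohorts

Scores are computed in log2 space: the arithmetic mean of log2
expression over the set's genes is algebraically the log2 geometric
mean of linear intensities.  Microarray-like values are strictly
positive, so no pseudocount is needed.  The final score subtracts the
mean raw score of the control (nephrectomy) samples, making the control
mean exactly 0 per set (enforced to 1e-9 in tests).  Duplicated gene
entries are dropped; genes missing from the expression table are
tolerated down to 50% coverage (refused below that, coverage always
reported).  Multiple probes per gene collapse by the mean of log2
values before scoring.

Median stratification computes the median over the **full** scored
population — not within a diagnosis — and crosses the resulting
above/below strata with diagnosis.  Ties at the median go to "below";
the choice is arbitrary but fixed, and only matters for exact ties.

Longitudinal trajectories select patients with ≥ 2 biopsies whose first
biopsy carries the index diagnosis (TCMR by default) and whose final
biopsy has resolved to no-rejection, and return the per-biopsy score
series for those patients.

## Spatial co-occurrence

The ratio at distance d is

    r(d) = P(type = B | cell within ≤ d of an anchor) / P(type = B),

computed from centroid Euclidean distances, where "within ≤ d of an
anchor" means within d of *some* anchor cell other than itself (union
of balls; each cell counted once; a lone anchor has no co-anchor).
Cumulative counting (≤ d) matches the direct-neighbor definition used
for testing; a per-annulus variant and a variant excluding the anchor
type from the neighbor pool are available behind flags.  The 25 µm
threshold defines direct neighbors; the qualitative
enrichment/depletion calls are stable across 15–30 µm (tested).

Across samples of the tested group (allogeneic/case sections by
default), the per-sample 25-µm ratios are compared with 1 by a
two-sided one-sample t-test; BH correction spans all (anchor, query)
pairs of one invocation.  Pairs with fewer than two finite per-sample
ratios are reported untested with the reason.  Degenerate zero-variance
ratio vectors return t = 0, p = 1 when centered at 1.

## Survival and composition statistics

Kaplan–Meier estimation and the two-group log-rank test are delegated
to lifelines; follow-up is administratively censored at 36 months (the
3-year graft-loss horizon, configurable) *before* estimation.  The
survival analysis takes one first biopsy per patient, splits each gene
set's score at the full-cohort median, tests above- vs below-median
within the primary diagnosis, and BH-adjusts across gene sets to report
fdr.  Compact letters for the four strata (diagnosis × median side)
come from pairwise log-rank tests BH-corrected within each set at 0.05,
assigned greedily: each stratum joins every existing letter group it is
not separable from, else founds a new letter.  Zero-event comparisons
return (statistic 0, p 1) rather than NaN.

Composition comparisons use the equal-variance Student's t (Welch is a
flag) with BH across cell types; an all-constant cell type returns
p = 1 and a degenerate flag.  The deconvolution-style variant
transforms proportions by `y = arcsin(√p)` and moderates the per-type
pooled variance with an empirical-Bayes prior whose scale s0² and
weight d0 (prior df) are estimated across cell types by the method of
moments on the F-distributed variance ratios (d0 = ∞, i.e. total
shrinkage, when the observed variance spread is no wider than sampling
noise; d0 floored just above 4 where the moment solution degenerates).
`prior_df=0` disables shrinkage and reproduces the ordinary t exactly;
`prior_df=inf` uses the pooled prior variance alone.  This is a
deliberately simple moderation — the testable contracts are the two
limits, not bug-for-bug agreement with any particular package.

Cross-dataset concordance selects the reference dataset's top-N most
increased and top-N most decreased genes by log2FC (N = 500 by default,
scaled down for small synthetic transcriptomes), intersects with the
other dataset's genes, and reports Spearman ρ — invariant under
monotone transforms of either fold-change vector.

## Synthetic data

All randomness flows from a single root seed through named SHA-256
substreams ("cells", "spatial:<sample>", "bulk"), so the three
generators are individually reproducible and mutually independent.

**Cell cohorts.**  Gene baseline means are drawn once from a lognormal
(σ = 1) and shared across populations; a planted marker multiplies its
gene's mean only inside its population (fold ≥ 1).  Per-cell library
sizes are log-uniform over 2,000–10,000 and counts are negative
binomial with one shared dispersion (θ = 2), the simplest model with
snRNA-seq-like overdispersion.  Cells are assigned uniformly at random
to samples (3 per group by default).  The reference design
(`default_config`): 5,000 cells, 2,000 genes, eight populations
(healthy PT/TAL, two PT injury states, TAL injury, macrophages, CD8 T,
fibroblasts); the target injury state carries 20 exclusive 4× markers
plus 5 genes shared with the adjacent injury state (planted in both at
4×, so the selection algorithm must reject them); every other
population has 15 exclusive 4× markers so that all populations are
separable in the embedding.

What this generator does *not* model: transcriptome-wide co-expression,
ambient RNA, doublets, batch effects.  Passing recovery tests therefore
shows the algorithm recovers planted mean-shift structure under NB
noise — not robustness to those artifacts.

**Spatial sections.**  Cells follow a homogeneous Poisson process
(density 0.005 cells/µm², 2 × 2 mm field ⇒ ~20,000 cells) with
multinomial type labels; section composition is configurable separately
from the dissociated-cohort proportions because tissue fractions and
nuclei fractions genuinely differ (reference design: 2% target injury,
10% macrophages).  For an enriched pair (A, B, ρ > 1), a calibrated
fraction q of B cells is placed uniformly inside the niche-radius disc
(25 µm) of a uniformly chosen anchor; for ρ < 1, B cells are thinned
within the discs with a calibrated retention.  The calibration solves

    u = ρ α (N − N_B) / (N − ρ N_B),   q = (u − α) / (1 − α)

where u is the probability that a B cell lies within the niche radius
of an anchor and α is the anchor-disc coverage of the field, measured
empirically by Monte Carlo against the realized anchor pattern (20,000
points from a dedicated substream) so that edge effects are absorbed.
This makes the *expected direct-neighbor ratio at the niche radius*
equal ρ — the enrichment parameter is defined operationally as the
statistic under test, which is what makes calibration testable (ρ = 2
is recovered within ±0.15 on single ~20,000-cell sections).  A query
type may appear in at most one enriched pair.

**Bulk cohorts.**  Per sample and gene set, a latent score s ~
N(μ_diagnosis, σ) (σ = 1 in the reference design; μ = 0.75 for
TCMR/Mixed, 0.5 for ABMR, 0 for NR — elevated in rejection but heavily
overlapping, as injury signatures are not rejection-specific) shifts
every set gene's log2 expression by s over a N(8, 1) gene baseline with
N(0, 0.15) residual noise (microarray-like technical variation).
Controls sit exactly at s = 0.  Graft-loss times are exponential with
log-hazard `log(rate₀) + Σ β_k s_k`, administratively censored at 36
months (optional uniform dropout).  Two helpers make study designs
explicit rather than tuned: `beta_for_median_split_hr(hr)` converts a
target hazard ratio between median-split halves of a normal score into
β (the halves' means differ by 2σ√(2/π)), and
`calibrate_baseline_rate(f, β)` solves the baseline rate for a target
event fraction by Monte-Carlo integration + Brent root-finding.  The
reference design uses HR 2.5 and 40% events at n = 300 with 4 controls
(the number of nephrectomy controls conventionally available).
Diagnosis prevalences default to NR 0.59 / ABMR 0.28 / TCMR 0.09 /
Mixed 0.04, the approximate mix of large transplant biopsy cohorts.
An optional longitudinal sub-cohort adds patients whose first biopsy is
TCMR, later biopsies NR, with the latent score held at 1.5 — the
persistence scenario for trajectory extraction.

## Problem sizes and runtime

The validation studies run at the reference sizes: 5,000-cell marker
recovery; 20 cohorts ≤ 500 cells for exact brute-force agreement of the
neighborhood machinery; 50 random patterns ≤ 2,000 cells for exact
agreement of the spatial machinery; one ~20,000-cell section for ρ
calibration plus 200 five-section CSR replicates (~2,000 cells each)
for the false-positive rate; 100 replicates of n = 300 for log-rank
power and 200 cohorts × 5 sets for the null fdr rate.  The full suite
and the acceptance script each complete in a few minutes on one CPU.

## Known limitations

* The neighborhood embedding (PCA-Euclidean) is a modeling choice, not
  a uniquely determined construction; marker sets can shift slightly
  under other embeddings.  The brute-force equivalence tests hold the
  embedding fixed and verify everything downstream of it.
* The spatial calibration formula is first-order in the anchor-coverage
  geometry; heavy anchor densities (coverage α approaching 1/ρ) make a
  requested enrichment geometrically unattainable and the generator
  will clip toward the feasible boundary.
* The moderated t is a simplified empirical-Bayes scheme; it matches
  ordinary t and prior-only limits exactly but is not a drop-in
  replacement for any specific published implementation.
* Wilcoxon p-values in the asymptotic regime omit the continuity
  correction; for the group sizes involved (tens to thousands) the
  difference is far below the decision thresholds used here.
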