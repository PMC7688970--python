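# Methods

This note documents the statistical procedures implemented in `capblood`,
the assumptions behind the synthetic-data generator, the parameter defaults
and why they were chosen, and the known limitations.

## Pipeline and data model

The unit of analysis is the **pseudobulk mean expression tensor**
μ[g, s, c, k]: the arithmetic mean of per-cell transcript fractions of gene
g over the cells of subject s, cell type c, sample k. Transcript fractions
are each gene's count divided by the cell's total count; no size factors,
variance-stabilizing transforms or highly-variable-gene selection are
applied. Tensor entries backed by fewer than `min_cells` cells (default 3)
are masked; a mean over one or two cells is dominated by sampling noise
and would feed a t-test meaningless observations. Setting `min_cells=1`
restores the fully literal behaviour.

The stage order is fixed: debris removal → pre-typing gene filter (max
count < 3 discarded) → embedding + cell typing → post-typing filter (gene
absent from 10% of every cell type discarded) → normalization → tensor →
tests. Fractions are computed after the post-typing filter, so each cell's
fractions are relative to its retained-gene total and rows sum to one.

## Debris removal

Three steps on the raw barcode × gene matrix:

1. **UMI threshold.** On a 50-UMI grid, the largest threshold retaining
   *more than* the expected number of cells. The expected count should
   overshoot the true cell count (the pipeline's default for simulated
   input is 1.15× the design target): the threshold must leave some debris
   above it, because step 3 *always* labels the faster-dropping trace
   group as debris — if only cell clusters remain, it will cut cells.
2. **Clustering.** PCA (20 components) of log(count+1), Ward agglomerative
   clustering, cluster number chosen over 6..15 by silhouette score. The
   conventional direction (maximize) is the default; a literal mode
   (minimize) is available as `paper_literal_silhouette` because the
   protocol this implements phrases the choice as a minimization, which
   contradicts the silhouette's definition (higher = better separation).
   The divergence is deliberate and surfaced, not silently resolved.
3. **Dropoff traces.** For each cluster, the number of member barcodes
   whose total UMI count is strictly above each grid threshold, normalized
   by cluster size; traces are 2-way Ward-clustered and the group with the
   smaller mean normalized area under the trace (faster dropoff) is
   removed as debris. Exact area ties are broken by labelling the group
   containing the lowest cluster id debris; identical traces produce no
   debris call.

## Cell typing

Cells are Ward-clustered in a 10-dimensional embedding. The default
embedding is PCA of the visualization transform log(5000·f + 1) of the
transcript fractions; the interface accepts an externally computed latent
space (e.g. a batch-conditioned variational autoencoder) with matching
barcodes, which is the supported path for batch correction — none is
performed internally. The cluster count is scanned from 13 to 15, stopping
at the first k at which every panel cell type is the argmax annotation of
at least one cluster ("separable" is operationalized as exactly this);
failing that, the k annotating the most types is used with a warning.
Cluster annotation scores each cluster against each panel type as the mean
(across the type's markers) of the cluster's mean expression standardized
across clusters; same-annotation clusters merge. The bundled panel carries
canonical PBMC markers (CD4/IL7R, CD8A/CD8B, NKG7/GNLY, CD14/LYZ,
FCGR3A/MS4A7, MS4A1/CD79A); it is user-overridable.

## Diurnal testing

Each subject's trace per (gene, cell type) is renormalized to a zero
equally weighted AM/PM mean by subtracting
(mean of available AM samples + mean of available PM samples)/2. Averaging
within each session class before weighting them equally preserves the
AM/PM balance when sessions are missing; subjects lacking a class entirely
are excluded for that (gene, cell type). The identity that the equally
weighted AM/PM mean of μ′ is exactly zero holds to machine precision and
is enforced by test.

The renormalized AM and PM values, pooled across subjects, are compared
with a classical pooled-variance two-sample t-test (subjects are fixed,
not random, effects; a Welch option exists). BH correction runs jointly
over the entire gene × cell-type grid. The per-gene plotting statistic is
a signed Z — sign(mean AM − mean PM) × |Φ⁻¹(p/2)| — taken at the minimum p
over cell types; the Z convention makes magnitudes comparable across cell
types with different sample counts. Degenerate zero-variance cases: equal
means give p = 1; unequal means give an infinite statistic, the smallest
positive double as p, and a `degenerate` flag.

The whole procedure is repeated with all cells pooled into one population
type (its own BH family). Crossing the two call sets classifies each gene:
significant per-type only (cell-type-specific), population only (suspected
abundance artifact), both, or neither. The population-only class is read
exclusively: a gene also significant in some cell type is never counted as
an artifact suspect. Suspected composition artifacts are checked directly
by a one-sided pooled t-test on per-sample cell-type fractions.

## Specificity ANOVAs

Subject specificity: per (gene, cell type), one-way ANOVA across subject
groups of per-sample means (requires ≥2 subjects with ≥2 samples).
Cell-type specificity: per gene, one-way ANOVA across cell-type groups of
per-sample means pooled over subjects. Both are BH-corrected at FDR 0.05
over their grids; the plotting statistic is log₂ F at minimum p.

## Pathway enrichment

The top n (default 250) genes by minimum diurnal p and the top n by
minimum subject p are united (ties at the cutoff are all kept, with a
warning); the remaining tested genes are the background. Each gene in ≥1
pathway weighs 1/(number of pathways containing it); genes in no pathway
are excluded from the universe. Per pathway, a two-proportion z-test
compares the weighted proportion of its genes in the top set vs the
background, with the weighted set totals as the effective sample sizes —
the natural composition of the stated weighting and test, documented here
as this package's convention. Category enrichment applies the same
statistic to category-pooled weighted counts (not averaged pathway z's).
Reported p-values are two-sided and deliberately uncorrected. Pathways
load from GMT files with a category sidecar TSV that can regroup top-level
classes (e.g. splitting disease pathways into immune-relevant subclasses);
there is no live database client.

## Synthetic data generator

Counts are gamma-Poisson (negative binomial): each cell's expected count
vector is library size × a gene-proportion vector. Proportions start from
a shared lognormal(0, 1.5) gene-weight vector and receive multiplicative
rate-scale effects before renormalization to sum to one — so planted
effects survive fraction normalization exactly as biological effects
would. Defaults (chosen once, as the emulated study conditions):

| parameter | default | rationale |
|---|---|---|
| subjects × days × sessions | 4 × 3 × AM/PM | the emulated design; missing sessions configurable |
| cells per subject-session | 1000 | study-scale (~1100 realized); scenarios scale down |
| library size | lognormal(ln 2500, 0.35) | typical droplet UMI depth |
| NB dispersion | 0.3 | mid-range scRNA-seq overdispersion |
| cell-type profile sd | 0.3 (lognormal) | genome-wide type identity beyond markers |
| session noise sd | 0.2 (lognormal, per gene × subject × session) | within-subject biological replicate variability; independent across subjects so pooled tests stay calibrated |
| composition | Dirichlet(500 × target) + multinomial | ~13% CV on a 10% type, consistent with day-to-day flow-cytometry variability |
| cell types | 6 PBMC types (30/20/8/20/6/16%) | canonical panel; NK at 8% serves as the minor host type |
| diurnal / subject effects | log2FC 2, 20 genes each mode | half the effect up in one class, half down in the other |
| abundance shift | B cells 0.10 (AM) → 0.16 (PM) | the emulated afternoon B-cell increase |
| debris | 600 barcodes at 0.1× UMI scale, ambient profile + 30% uniform | low-UMI ambient droplets |

The NK fraction of 8% is a designed choice: with a 4× within-type effect,
a host type at fraction φ dilutes the pooled log-effect to
ln((1−φ+2φ)/(1−φ+φ/2)); at φ = 0.10 the pooled noncentrality (~1.8 given
the session noise) leaves a non-trivial chance of pooled significance,
while at φ = 0.08 the restricted genes stay reliably below the joint-BH
threshold — which is the dilution phenomenon the per-type analysis exists
to overcome.

What the generator does **not** emulate: read-level structure (no FASTQs),
ambient contamination inside retained cells, doublets, batch effects
between sessions (real batch correction must come through the external
embedding hook), tag-count zero inflation beyond NB, or gene-gene
correlation. Passing tests therefore show that the procedures are
correctly implemented and calibrated under an NB world with independent
genes — not that any particular biological discovery is reproducible.

## Benchmark scenario sizes

Scenario problem sizes (in `capblood.scenarios`) were fixed so a full
sweep runs in minutes on one CPU:

- null type-I: 2000 genes, 3 identical cell types, 60 cells/sample,
  200 replicates; rejection fractions compared to 0.05 + 3 binomial SE;
- recovery: 1000 genes, 400 cells/sample, one replicate (40 diurnal + 20
  subject genes give tight binomial margins at 80%);
- abundance confound: 400 genes, 600 cells/sample, 15 B-exclusive genes
  (64×; genes of this kind are essentially confined to B cells), 50
  replicates; success is the gene-level reproduction of the artifact
  (≥1 population-only call on a B-dominant gene, zero per-type calls,
  abundance test p < 0.05);
- debris: 300 genes, 100 cells/sample + 600 debris barcodes, 10 seeds,
  expected cells = 1.15× the true count;
- typing: 500 genes, 100 cells/sample (2400 cells), default panel.

## Known limitations

- Embedding and clustering densify the matrix; at the ~10⁴-cell scale of
  the emulated studies this is comfortable, but 10⁵+ cells would need a
  sparse PCA path.
- Subjects are treated as fixed effects and samples as exchangeable within
  session class; there is no mixed-effects or permutation machinery, and
  no cosinor-style curve fitting — AM vs PM only.
- The trace-based debris step assumes debris is present among the
  above-threshold barcodes; with an exact expected-cell count it can cut
  real cells (see Debris removal above).
- Weighted two-proportion effective sample sizes are a convention; other
  compositions of the weighting and the z-test are defensible.
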