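# capblood

Cell-type-resolved diurnal and subject-specific gene detection for
multiplexed capillary-blood single-cell RNA-seq.

## The problem

Repeated capillary blood sampling (e.g. morning and afternoon over several
consecutive days) makes it cheap to profile a person's circulating immune
cells at single-cell resolution. Analyzing such a study raises questions
that bulk pipelines do not answer:

- which genes change between morning (AM) and afternoon (PM) *within a
  specific immune cell type*, and which only appear to change at the
  whole-population level because a cell type's **abundance** shifts during
  the day;
- which genes differ stably **between subjects**, within which cell types;
- which pathways are enriched among the most time- and subject-varying
  genes.

`capblood` implements the full chain for droplet scRNA-seq count matrices:
debris-droplet removal by barcode dropoff traces, gene filtering, per-cell
fraction normalization, marker-based cell typing in a pluggable embedding,
pseudobulk mean expression, AM-vs-PM testing with abundance-shift
disambiguation, subject/cell-type specificity ANOVAs, and weighted pathway
enrichment. A synthetic-data generator with a planted ground-truth registry
emulates the study design end to end, so every stage is testable against
known truth.

## The model

All tests run on the pseudobulk mean expression tensor
μ<sub>g,s,c,k</sub>: the mean transcript fraction of gene *g* over the
cells of subject *s*, cell type *c*, in sample (session) *k*. Stable
between-subject differences are removed before diurnal testing by
renormalizing each subject's trace to a zero equally weighted AM/PM mean:

    μ′_{g,s,c,k} = μ_{g,s,c,k} − ( mean_AM μ_{g,s,c,·} + mean_PM μ_{g,s,c,·} ) / 2

The pooled AM and PM μ′ values are compared per (gene, cell type) with a
two-tailed classical (pooled-variance) t-test, with Benjamini–Hochberg
correction applied jointly over the whole gene × cell-type grid at FDR
0.05; repeating the procedure with all cells pooled into one population
gives the whole-population calls, and crossing the two call sets classifies
each gene as cell-type-specific, population-only (a suspected abundance
artifact), both, or neither. A one-sided t-test on per-sample cell-type
fractions verifies suspected composition shifts. Subject and cell-type
specificity use one-way ANOVAs on per-sample means (plotting statistic:
log₂ F at the minimum p over cell types). Pathway enrichment weights each
gene by 1/(number of pathways containing it) and applies a two-proportion
z-test of the top-250-per-axis gene set against the background.

## Worked example

```python
from capblood import (SimConfig, generate_dataset, normalize,
                      filter_genes_pre, build_tensor, DiurnalModel,
                      classify_diurnal)
from capblood.simulate import design_from_config, true_annotation

config = SimConfig(n_genes=800, cells_per_sample=400, seed=2,
                   debris=None, abundance_shift=None)
matrix, annotation, truth = generate_dataset(config)
annotation = true_annotation(annotation, truth)   # ground-truth cell types
design = design_from_config(config)

norm = normalize(filter_genes_pre(matrix))
tensor = build_tensor(norm, annotation, design)
pooled = build_tensor(norm, annotation, design, pooled=True)

celltype = DiurnalModel(tensor, design).fit()
population = DiurnalModel(pooled, design).fit()
print(len(celltype.significant_genes()), "diurnal genes in >=1 cell type")
print(len(population.significant_genes()), "diurnal genes at population level")
```

prints

```
49 diurnal genes in >=1 cell type
23 diurnal genes at population level
```

The configuration plants 20 globally diurnal genes and 20 diurnal only in
NK cells (8% of cells). The per-type analysis recovers 39 of the 40
(plus a handful of borderline false positives at FDR 0.05), while the
population-level analysis sees essentially only the global ones — the NK
signal is diluted ~12-fold below its significance threshold. That gap is
the package's central point: cell-type-resolved testing finds diurnal
genes that population-level analysis misses.

The same objects drive the scatter layouts via `capblood.plotting`, and
`truth.diurnal_genes` identifies exactly which detections are planted.

## Command line

```bash
capblood all --config run.yaml --out results/
```

runs simulate/ingest → debris removal → gene filtering → cell typing →
pseudobulk → diurnal + specificity tests → classification → enrichment,
persisting each stage's TSV and a `summary.json`. Individual stage
commands (`capblood debris`, `capblood diurnal`, ...) run the pipeline up
to that stage from the same config. A minimal config:

```yaml
simulate:
  n_genes: 1000
  cells_per_sample: 400
seed: 1
```

For real data replace `simulate:` with `input_dir:` pointing at a
10x-style directory (`matrix.mtx`, `barcodes.tsv`, `features.tsv`,
`metadata.tsv` with barcode/subject/day/session columns) and set
`expected_cells`.

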