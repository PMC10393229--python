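# npxtools

Discovery–replication analysis of Olink-style plasma proteomics, built for
studies comparing virally suppressed people living with HIV (PLHIV) against
healthy controls (HC) — and for anyone running a two-cohort NPX differential
expression study with downstream origin, pathway, microbiome and
cardiovascular-outcome analyses.

NPX (Normalized Protein eXpression) is a relative, log2-scale protein
quantification unit with a per-assay limit of detection (LOD). The package
covers the full analytic chain:

* **qc** — assay deduplication (technical-control proteins measured on every
  panel), vendor-style sample QC (mean assay counts ≥ 500, control deviation
  within ±0.3 NPX), below-LOD protein filters (two-group and single-group),
  PCA outlier exclusion (|PC1/PC2 − mean| > 3 SD), plate CVs.
* **diffexp** — per-protein OLS of NPX on group + age + sex + smoking, with
  empirical-Bayes variance moderation: the posterior residual variance is
  `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` and the moderated
  `t̃_g = β_g/(c_g s̃_g)` is referred to a t-distribution on `d₀ + d_g` df
  (Smyth's moment-matching estimate of `d₀, s₀²`); Benjamini–Hochberg FDR;
  the replicated-DEP call (discovery FDR < 0.05, replication P < 0.05, same
  sign); the PC1/PC2 Mann–Whitney group-separation test.
* **enrich** — one-sided hypergeometric enrichment
  `P = Σ_{i≥k} C(K_b,i)C(N_b−K_b, n−i)/C(N_b,n)` of a candidate list
  against the measured-protein background, for tissue/cell-origin categories
  (eligible when K_b > 3) and GMT gene sets (significant when P < 0.05 and
  overlap > 3).
* **pathnet** — enrichment map: pathways joined when the overlap score
  (mean of Jaccard and overlap coefficients) exceeds 0.375, clustered with a
  deterministic Markov cluster algorithm (expansion 2, inflation 2) and
  auto-labelled by name-token frequency.
* **assoc** — covariate-adjusted linear, logistic (odds ratio per SD of
  NPX) and partial-Spearman association engines; centered log-ratio
  transform and 20% prevalence filter for compositional microbiome tables;
  group-wise comparison of significant-association proportions (pairwise
  χ²); Fisher set enrichment; the two-stage (FDR, then replication)
  CVD screen; three-set overlap counts.
* **synth** — a fully seeded generator of every input with known ground
  truth: two cohorts with planted, direction-consistent effects,
  covariate structure, LODs, control-assay duplicates, outlier samples, a
  specificity map with a planted enriched tissue, themed gene sets,
  a compositional microbiome with planted protein–species links, and
  logistic CVD outcomes with planted driver proteins.
* **pipeline / cli** — one seeded YAML-configured run of the whole chain
  (`npxtools run-all --outdir out`), persisting every intermediate table.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/02_qc_and_differential_expression.py` prints:

```
discovery: removed 9 duplicate control assays, 7 PCA outlier samples, 131 below-LOD proteins; 269 proteins x 193 samples into the model
replication: removed 9 duplicate control assays, 4 PCA outlier samples, 130 below-LOD proteins; 270 proteins x 276 samples into the model

sDEPs called: 45 (44 up, 1 down)
recall of planted DEPs: 0.75; false calls: 0
sDEPs with |log2 fold-change| >= 1.5 in BOTH cohorts: 2
```

Read: of 400 synthetic proteins (409 assays before deduplication), 130 fail
the below-LOD filter; the moderated two-cohort analysis then recovers 75% of
the 60 planted differentially expressed proteins with no false calls, and
two of the calls exceed a 1.5 log2-NPX shift in both cohorts — the
"fold-change" here being the covariate-adjusted difference in mean log2 NPX
between groups. The other examples demonstrate cohort generation, tissue
enrichment plus the clustered pathway map, and the microbiome/CVD
association engines.

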