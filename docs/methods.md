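# Methods

## The analytic model

The core quantity is the covariate-adjusted difference in mean log2 NPX
between PLHIV and healthy controls, estimated per protein by ordinary least
squares on the design `[1, group, age, sex, smoking]`. Samples missing any
covariate are removed listwise before fitting. Because a plasma panel
measures thousands of proteins on a few hundred samples, per-protein
residual variances are noisy; they are shrunk toward a pooled prior by the
empirical-Bayes moment-matching scheme of Smyth (2004): writing
`z_g = log s²_g` and `e_g = z_g − ψ(d_g/2) + log(d_g/2)`, the prior degrees
of freedom solve `ψ′(d₀/2) = 2·(var(e) − mean ψ′(d_g/2))⁻¹`-style trigamma
matching (monotone bisection; no positive solution ⇒ `d₀ = ∞`, full
shrinkage to `s₀²`), and the moderated t uses `d₀ + d_g` degrees of freedom
capped at the pooled residual df, exactly as the reference Bioconductor
implementation does (the test suite pins the agreement to ~1e-9 against a
frozen limma fit). Two-sided P values throughout; Benjamini–Hochberg FDR
within each analysis family, never pooled across families.

A protein is a replicated (shared) DEP when discovery FDR < 0.05,
replication P < 0.05, and the effect sign agrees in both cohorts. The
"fold-change ≥ 1.5" subset applies the threshold to the log2-NPX difference
in *both* cohorts (a linear-scale variant, `2^|β| ≥ thr`, is exposed because
the phrase is ambiguous in common usage).

## QC conventions

Below-LOD fractions use strict `NPX < LOD`; NPX values below LOD are used
as delivered, never masked or imputed, since the platform reports
extrapolated values. Boundary conventions: "greater than 25%" strict,
"within ±0.3" inclusive, "at least 500" inclusive, "less than 20%" strict.
The two-group filter's second clause is interpreted as the difference in
below-LOD *sample fractions* between groups (< 20 percentage points) — a
difference of per-assay LOD constants between participant groups is
undefined for a shared assay. Proteins are z-scored before the outlier PCA
(configurable off); outlier flagging is a single pass. Plate CVs are
computed on linearized values (2^NPX), intra = mean within-plate CV%,
inter = CV% of plate means.

## Enrichment and the pathway network

Enrichment is the one-sided upper hypergeometric tail, inclusive of the
observed k, summed in log space. The background is always the measured
panel (1,463-protein analog), never the genome. Categories need more than 3
background members to be eligible; FDR is computed separately within tissue
and cell categories (the joint alternative is a flag). ORA significance
additionally requires an overlap of more than 3 candidate proteins. The
plain hypergeometric is the default; a `mode="ease"` option computes the
conservative k−1 variant for compatibility with DAVID-style EASE scores.

The enrichment map joins two significant pathways when
`(J + O)/2 > 0.375` (strict), with J the Jaccard and O the overlap
coefficient of their member sets. MCL runs on the weighted adjacency with
self-loops set to each node's maximum incident weight (1 for isolated
nodes), column normalisation, expansion 2, inflation 2, convergence when
the transition matrix changes by < 1e-6, 100 iterations max;
non-convergence returns the current partition flagged. Attractor rows
define clusters; overlapping supports merge, so the output is always a
partition. Inflation and the self-loop scheme are conventional choices —
cluster counts are sensitive to them and are not treated as reproducible
quantities. Cluster labels are the three most frequent non-stopword name
tokens (alphabetical tie-break), a deliberate simplification of word-cloud
annotation tools.

## Association engines

Regression orientation: for immune-cell proportions (log2-transformed) and
CLR microbiome abundances the feature is the response and NPX the
predictor; for baseline CVD the protein is the response with the CVD
indicator as predictor (mirroring the group-difference framing of the DE
model); for incident CVD the event is the response of a binomial logistic
model (Newton/IRLS, tolerance 1e-8, 50 iterations) adjusted for age, sex,
BMI, smoking, dyslipidemia, hypertension and type-2 diabetes. NPX is
standardised to unit SD within the analysis sample before logistic fitting,
so odds ratios are per SD (per-unit available); perfect separation and
constant predictors yield flagged rows, not crashes. The bulk linear engine
uses Frisch–Waugh–Lovell residualisation, which is exact OLS, so one pass
covers every (feature, protein) pair. Partial Spearman = Pearson
correlation of rank residuals after OLS on the covariates, with
`df = n − 2 − #covariates`. CLR uses a global half-minimum-nonzero
pseudocount by default (a float pseudocount and multiplicative alternatives
are exposed); prevalence keeps species present in ≥ 20% of samples. The
group-proportion comparison uses uncorrected 2×2 χ² tests, reported
unadjusted, as post-hoc pairwise tests conventionally are.

## What the generator emulates — and what it does not

The generator reproduces the *structure* that the analysis chain must cope
with: two cohorts (pre-QC 211 + 122 and 642 + 100 participants) whose PLHIV
arms are older, more male (80% vs 65%) and more often smokers (30% vs 13%)
than their controls, so covariate adjustment genuinely matters; 1,463
unique proteins on four panels with IL6/CXCL8/TNF duplicated onto every
panel as tightly correlated technical copies (1,472 assays); 276 true DEPs
with identical signed effects in both cohorts, ~96% upregulated; 150
low-detection proteins whose LOD sits at the pooled 32% quantile so the
below-LOD filter engages; 5+2 and 3+1 planted outlier samples shifted by
6 noise-SD on every assay; a planted intestine tissue over-represented
4-fold among true DEPs; themed, overlapping planted gene sets (lipid /
chemokine / antigen triplets) so the enrichment map develops real cluster
structure; ~150 protein–species links concentrated on a small pool of
intestine-specific DEPs and prevalent species, each species consistently
enriched or depleted; and binary CVD outcomes from a logistic model with a
10% event rate, classical risk-factor coefficients and ln 3 per-SD
log-odds on ten driver proteins.

Magnitudes are calibration choices, not estimates of any real cohort: the
underlying study does not publish effect sizes, so the default effect
distribution (|N(0.6, 0.2)| log2-NPX at noise SD 1, with a 16/276 fraction
of large ~1.8 shifts mimicking the heavy lipid-transport tail) was chosen
once as a realistic mid-power regime and left alone. Real NPX data have
heteroskedastic, correlated proteins, batch and plate effects, non-Gaussian
tails and LOD-censored reporting artefacts — none of which are modelled.
Passing tests therefore certify the *pipeline logic* (bookkeeping,
calibration under its own noise model, recovery of planted signal), not
performance on real plasma data.

## Numerical and design choices

* Every artefact is a deterministic function of one integer seed via
  per-stream `SeedSequence` children; cohorts share their truth stream.
* The logistic intercept of the outcome model is tuned by root-finding so
  the expected event rate equals the configured base rate exactly.
* Hypergeometric tails sum `exp(logpmf)` with `logsumexp`; tails covering
  the whole support return exactly 1.
* Trigamma inversion is monotone bisection to 1e-12, deterministic.
* BH ties: adjusted values depend only on the P vector; row order is
  stabilised by sorting tables on protein id.
* Zero residual variances are excluded from prior estimation and produce
  infinite moderated t (P = 0) — surfaced, not hidden.
* Degenerate inputs (constant proteins in PCA, all-zero microbiome rows,
  single plates) are either dropped with a warning or reported missing
  rather than raising.

## Problem sizes used by the test suite and acceptance script

Unit tests run on 150–400-protein cohorts of 100–280 samples. Calibration
and recovery checks use 1,300-protein null cohorts (10 seeds), the
200-planted-DEP design at 200+100 / 600+100 samples (10 seeds), annotation
recovery at the full 1,463/276 scale (10 seeds) and the logistic model at
n = 2,000 (20 seeds); the acceptance script uses the same designs with
modestly fewer seeds plus one full default-scale pipeline run. These sizes
were chosen so the whole suite completes in a few minutes on one CPU while
keeping every check at the scale where its statistical claim is meaningful.

## Known limitations

* No batch/plate covariates, mixed models or surrogate variables; the
  design matrix is the fixed covariate set.
* The microbiome model is compositional closure over thinned lognormals —
  no sequencing-depth noise model beyond a lognormal read-count column.
* MCL cluster counts depend on inflation; only structural properties
  (partition validity, block separation, reference parity) are asserted.
* The CVD analyses treat the 5-year outcome as binary; no time-to-event
  modelling.
* Immune-cell proportion tables are not generated; the generic linear
  engine covers that analysis (see examples).
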