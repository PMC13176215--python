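# Methods

`cdikit` re-implements, as a tested pipeline over synthetic data with known
ground truth, an analysis that converts multi-cohort cartilage
gene-expression profiles into a continuous Cartilage Degradation Index
(CDI) and explains that index gene-by-gene and pathway-by-pathway. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic experiments do and do not demonstrate.

## The analysis in one paragraph

Several independent log2-scale expression datasets (microarray- and
RNA-seq-like) are harmonized by per-dataset quantile normalization,
gene-set intersection and parametric empirical-Bayes batch correction.
Differentially expressed genes (DEGs) between osteoarthritic and
non-osteoarthritic cartilage are selected by Welch's t-test with
Benjamini–Hochberg (BH) control at FDR < 0.05 and |log2FC| > 0.5 (both
strict). On those genes a soft-voting ensemble — random forest,
gradient-boosted trees (XGBoost) and an RBF/linear SVM with Platt-style
probability calibration — is tuned by randomized search and evaluated with
stratified 5-fold cross-validation, scaling fitted strictly inside each
fold. The ensemble's class-1 probability, the arithmetic mean of the three
base probabilities, is used directly as the CDI on a 0–1 severity scale
with risk zones [0, 0.2] low, (0.2, 0.5] intermediate, (0.5, 0.8) elevated,
[0.8, 1] high. Robustness is assessed by a label-permutation test of the
cross-validated AUC and percentile bootstrap intervals on pooled
out-of-fold predictions. Shapley attributions are computed per base model
and averaged into a consensus matrix; derived from it are global mean-|SHAP|
gene rankings, cross-cohort Spearman consistency, a per-gene
mechanosensitivity score from a strain-vs-control cohort, and an
attribution-weighted pathway score alongside Fisher's-exact
over-representation analysis (ORA).

## Synthetic cohort generator

The generator (`cdikit.synthetic`) is first-class, tested code; every
downstream stage is validated against its planted truth. For gene *g*,
sample *s* in batch *b*:

```
y[g,s] = mu_g + grade(s) * sign(g) * effect_g * 1[g in DEG]
       + strain(s) * strain_effect * 1[g in mechano]
       + gamma[b,g] + delta[b,g] * eps,      eps ~ N(0, noise_sd)
```

with `mu_g ~ U(4, 12)` log2 units, additive batch shifts
`gamma ~ N(0, batch_shift_sd)` and multiplicative batch factors
`delta = exp(N(0, batch_scale_sd))` — exactly the location/scale form the
batch corrector assumes, so correction is testable as parameter recovery.
Model-misspecification robustness is deliberately out of scope.

Defaults and why:

- **7 batches**: six tissue datasets (the first three in the training
  role, the rest validation) plus one strain-vs-control mini-cohort,
  mirroring a seven-dataset, train/validate/mechanotransduction design.
- **Degradation grades** {healthy 0.0, early 0.4, advanced 1.0}; the
  training label is binary with class 1 iff grade ≥ 0.5, so early-damage
  samples are trained as "non-disease" but should land mid-spectrum at
  prediction time — this is the property the CDI is meant to expose.
- **93 planted DEGs, 74 up / 19 down**, |log2FC| = 1.0 at full grade
  (comfortably past the 0.5 selection gate); **16 strain-responsive**
  genes among them, echoing a 7 + 9 high/moderate mechanosensitive
  structure.
- **Strain-responders are the strongest disease drivers**
  (`mechano_deg_boost = 2.0`, i.e. planted |log2FC| 2.0 vs 1.0): in the
  motivating analyses the top attribution-ranked genes and the top
  mechanosensitive genes coincide, and an attribution-difference score can
  only rank genes the model actually attends to (see Limitations).
- **Sample sizes**: 10 healthy / 4 early / 10 advanced per dataset plus
  9 + 9 strain samples (162 total, 72 training) — a desk-scale analogue of
  a ~200-sample, ~120-training-sample study.
- **Noise** `noise_sd = 0.5` log2 units, typical residual within-group
  spread for normalized expression data; `batch_shift_sd = 2.0` makes PC1
  batch-dominated before correction, reproducing the
  "PC1 ≈ 80% of variance, clustered by dataset" failure mode.
- `n_genes = 2000` as a desk-scale stand-in for a ~10,000-gene
  cross-platform intersection.

The generator does **not** emulate count-level sequencing noise (negative
binomial, library sizes), probe-level microarray structure, correlated
gene modules, or batch effects outside the additive/multiplicative family.
Passing tests therefore demonstrate correctness of the machinery under its
stated model, not performance on real cartilage data.

## Harmonization

Quantile normalization forces every sample column onto the per-rank mean of
the sorted columns; ties receive the mean of the reference values over the
tied span (deterministic and order-independent; exact idempotence holds on
tie-free data). The batch corrector implements the standard parametric
empirical-Bayes location/scale algorithm with an intercept-only model:
gene-wise standardization against pooled mean/variance, per-batch
additive/multiplicative estimates, moment-matched normal and inverse-gamma
priors, and iterative posterior updates to tolerance 1e-4 (max 100
iterations), with a 1e-8 variance floor for degenerate genes. It matches
Bioconductor's reference implementation to ~1e-13 on shared fixtures (the
test suite runs that cross-check through `Rscript`). No biological
covariates are protected during correction — the conservative reading when
a study is silent on the point; group structure must survive correction on
its own. Batch diagnostics report PC1's variance share and the one-way R²
of batch on PC1 scores.

## Differential expression

Welch's unequal-variance t-test (two-sided) per gene, vectorized; genes
with zero variance in both groups receive p = 1 so BH stays well defined.
BH is the classic step-up estimator. Selection uses strict inequalities at
both gates, so a gene at exactly |log2FC| = 0.5 or FDR = 0.05 is excluded.
Moderated-variance (limma-style) testing and covariate adjustment are
non-goals.

## Ensemble and CDI

Hyperparameter spaces: RF `n_estimators` 100–500, `max_depth`
{3,5,7,10,∞}, `max_features` {sqrt, log2, 0.3–0.7}; XGBoost `n_estimators`
50–400, `max_depth` 2–8, `learning_rate` 0.01–0.31 (log-uniform),
`subsample` 0.5–1.0; SVM `C` 0.01–50 and `gamma` 1e-4–1e-1 (both
log-uniform), kernel {rbf, linear}. Randomized search (default 80 draws)
uses an inner stratified 3-fold split of the training data only; the outer
evaluation fold never touches the standardizer or the search. SVM
probabilities come from sigmoid (Platt) calibration fitted on the training
split. The ensemble probability is exactly the unweighted mean of the
three base probabilities — asserted bitwise in tests.

Metrics on pooled out-of-fold predictions: rank-formulation AUC with tie
correction, Brier score, and accuracy/precision/recall/F1 at threshold
0.5. The train-CV AUC gap is reported as an overfitting indicator. The
ablation evaluates all 7 non-empty model subsets on the same out-of-fold
probabilities. Fold assignment is keyed to sorted sample ids, making
out-of-fold results invariant to input row order. A fixed "light"
configuration (40-tree forest, 40-round depth-2 booster, default-RBF SVM)
is used where the search is not the object of study — permutation nulls
and quick cross-validation — keeping a single permutation CV under ~0.5 s.

The interval (0.5, 0.8) is labeled "elevated"; the neighbouring zone names
follow the low/intermediate/high convention, and the unnamed band needed a
label for the zone map to be total.

## Robustness

The permutation test shuffles labels *before* fold assignment each
iteration and reruns the entire CV, with the smoothed estimator
p = (1 + #{permuted ≥ true}) / (n_iter + 1), so p ≤ 0.001 at 1,000
iterations occurs only when no permutation beats the observed AUC.
Bootstrap intervals resample out-of-fold (label, probability) pairs with
replacement within each class (every replicate keeps both classes) and
report percentile intervals; refitting models per replicate is available
but not the default, since pair-resampling is the only variant that is
cheap at 1,000 iterations.

## Attribution

- **Random forest**: in-package path-dependent Tree SHAP (the
  polynomial-time EXTEND/UNWIND algorithm) on each tree's class-1
  probability, averaged over trees. Exact: attributions plus the
  cover-weighted root expectation reproduce the forest probability to
  machine precision, and on small trees they equal exhaustive-coalition
  Shapley values of the tree's conditional-expectation value function.
- **XGBoost**: the booster's native Tree SHAP (`pred_contribs`), which
  explains the log-odds margin; attributions are rescaled per sample by
  (p − expit(base)) / (margin − base) so they sum exactly to the predicted
  probability. The rescaling preserves signs and per-sample proportions
  but is a pragmatic bridge between margin-space and probability-space
  additivity, not itself a Shapley operation.
- **SVM**: in-package Kernel SHAP. All 2^M − 2 coalitions are enumerated
  when that fits the budget; otherwise coalition sizes are sampled from
  the Shapley kernel and members uniformly. Coalition values are means
  over a class-stratified background (default 50 training samples) with
  coalition features imputed from the explained sample. The weighted least
  squares is solved with the efficiency constraint eliminated, so local
  accuracy holds exactly even under sampling; accuracy of individual
  attributions grows with the coalition budget (default 1000; 2000 for the
  mechanosensitivity analysis).

The consensus matrix is the unweighted elementwise mean of the three
(matching the 1/3 voting weights); by linearity its local accuracy against
the soft-vote probability follows from the base models'. Global importance
is the per-gene mean of absolute attributions, ranked descending with
lexicographic tie-breaks. Cross-cohort consistency reports pairwise
Spearman correlations of importance vectors and per-gene top-20 membership
counts.

**Mechanosensitivity**: per gene, the absolute difference between mean
consensus attribution in strained and control samples, min-max normalized
over all analyzed genes, categorized with strict cuts — score > 0.6 high,
score < 0.3 low, boundary values (exactly 0.3 or 0.6) moderate. If every
gene has the same raw difference the scores are all set to 0 with a
warning.

## Pathway analysis

ORA uses the one-sided hypergeometric upper tail P(X ≥ k) — equivalent to
one-sided Fisher's exact — with BH correction across each collection and
term-size limits 3–500. The background universe is the measured
common-gene set, not the whole genome: enrichment should be judged against
what could have been detected. Collections are read from local GMT files;
no web service is contacted. The attribution-weighted pathway score is the
mean global importance of a term's genes within the model's feature set
(0, flagged, when the intersection is empty); it deliberately ranks terms
by their contribution to the model's decisions, which can disagree with
significance-based ranking — the test suite constructs such a case.

## Problem sizes used by the automated checks

The permutation checks run on a single-batch balanced cohort of 120
samples with 93 signal genes (planted effect 1.0 for the null-centering
check, 1.5 for the significance check), 200 and 1,000 permutations
respectively, with the light model configuration. Batch-correction
recovery uses 500 genes, two batches of 100; DEG calibration uses 2,000
genes at 30 samples per group over 20 null replicates; attribution oracles
use 3-feature trees where exhaustive enumeration is exact. These sizes
were chosen so each property is measured well inside its Monte-Carlo
tolerance while the whole suite stays desk-scale.

## Known limitations

- The mechanosensitivity score measures the *model's* response to strain,
  not the transcriptome's: a strain-responsive gene the classifier ignores
  produces no attribution difference and is invisible to the score.
  Recovery of planted responders is therefore only high when the
  responders are also strong disease markers (the regime the generator's
  default emulates); with responders drawn uniformly from equal-effect
  DEGs, recovery plateaus near 0.6–0.75 and the top false positives are
  the globally most important genes amplifying small-sample noise.
- Path-dependent Tree SHAP conditions on tree traversal statistics, so
  correlated features share credit in tree-structure-dependent ways; the
  kernel explainer's background imputation assumes feature independence.
- The permutation and bootstrap procedures quantify chance and sampling
  variability, not transportability to differently distributed cohorts.
- Quantile normalization's tie rule breaks exact idempotence on data with
  ties (re-application re-mixes the reference); the effect is bounded by
  the tie structure and absent on continuous data.
- The single canonical out-of-fold AUC is reported; no attempt is made to
  reconcile small discrepancies that arise between differently pooled
  summaries of the same CV run.
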