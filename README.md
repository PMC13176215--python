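# cdikit — a continuous Cartilage Degradation Index from multi-cohort transcriptomics

Osteoarthritis research increasingly treats cartilage breakdown not as a
binary sick/healthy label but as a continuum: healthy tissue, early
mechanical damage (e.g. after partial meniscectomy), advanced structural
disease. `cdikit` implements, end to end and on fully synthetic data with
known ground truth, an analysis pipeline that turns heterogeneous
gene-expression cohorts into such a continuum — the **Cartilage
Degradation Index (CDI)** — and then explains the index at the gene and
pathway level. It is aimed at computational biologists who want a tested,
reusable implementation of this class of analysis (harmonize → select →
classify → calibrate a severity score → attribute) without depending on
any external download.

The pipeline stages, each its own module under `src/cdikit/`:

1. **synthetic** — multi-batch expression generator with planted batch
   effects, differentially expressed genes (DEGs), a graded degradation
   spectrum and a strain-vs-control mini-cohort; every stage is testable
   against the planted truth.
2. **harmonize** — per-dataset quantile normalization, gene intersection,
   parametric empirical-Bayes batch correction (each dataset a batch), and
   PCA batch diagnostics.
3. **deg** — Welch's t-test, Benjamini–Hochberg FDR, and dual-threshold
   selection: FDR < 0.05 and |log2FC| > 0.5.
4. **ensemble** — random forest + XGBoost + Platt-calibrated SVM, tuned by
   randomized search under stratified 5-fold CV with in-fold scaling. The
   soft-vote probability

   `CDI(x) = (p_RF(x) + p_XGB(x) + p_SVM(x)) / 3  ∈ [0, 1]`

   is the index, with risk zones [0, 0.2] low, (0.2, 0.5] intermediate,
   (0.5, 0.8) elevated, [0.8, 1] high.
5. **robustness** — label-permutation test of the cross-validated AUC with
   the smoothed estimator `p = (1 + #{AUC_perm ≥ AUC_true}) / (n + 1)`,
   and stratified percentile bootstrap CIs on out-of-fold predictions.
6. **attribution** — Shapley values per base model (in-package
   path-dependent Tree SHAP for the forest, XGBoost's native tree
   attributions rescaled to probability space, in-package Kernel SHAP for
   the SVM), averaged into a consensus matrix; global mean-|SHAP|
   rankings, cross-cohort Spearman consistency, and a per-gene
   **mechanosensitivity score**
   `|mean SHAP(strain) − mean SHAP(control)|`, min-max normalized, with
   categories high (> 0.6) / moderate (0.3–0.6) / low (< 0.3).
7. **pathways** — Fisher's-exact over-representation analysis against GMT
   collections with BH correction, run overall and per direction, plus a
   SHAP-weighted pathway score (mean importance of a term's genes within
   the feature set).
8. **pipeline / cli** — a single-config orchestrator (`cdi run`) plus
   per-stage subcommands.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (2000 genes; six tissue datasets, 162 samples, with a
9-vs-9 strain mini-cohort; 93 planted DEGs of which 16 respond to strain):

```bash
cd analysis
python 01_simulate_cohorts.py
python 02_harmonize.py
python 03_differential_expression.py
python 04_train_cdi.py
python 05_robustness.py
python 06_attribution.py
python 07_pathways.py
```

Selected output (deterministic for the committed seed):

```
PC1 variance share: 17.3% -> 5.1%
batch R2 on PC1:    1.000 -> 0.000
selected 93 genes (74 up, 19 down) of 2000 tested
sensitivity vs planted truth: 1.00; false discoveries: 0

CDI by condition:
 advanced 0.943   healthy 0.010   early 0.057
 strain   0.374   control 0.161

true AUC 1.000, mean permuted 0.503, p = 0.004975 (200 permutations)

cross-cohort Spearman rho of importance vectors:
            train  validation  strain
train       1.000       0.982   0.941

planted strain-responder recovery in top-16: 0.88
6 of 40 terms significant at FDR < 0.05 (all six planted enriched sets)
```

Reading it: batch structure dominates the first principal component before
correction and is gone afterwards; the DEG stage recovers exactly the
planted 74 up / 19 down genes; the CDI orders the degradation spectrum
(healthy < early < advanced) on held-out samples and separates strained
from control chondrocyte-like profiles; gene-importance rankings are
stable across cohorts; and the mechanosensitivity score places 14 of the
16 planted strain-responsive genes in its top 16. Small summary tables are
written to `results/analysis/`, large intermediates to
`scratch/analysis_data/`.

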