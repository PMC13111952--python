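# Methods

## Scope and data model

`peptidia` operates on a peptide (or protein) × sample intensity grid
with an explicit missing mask (`NaN`), per-feature annotation (parent
protein, sequence, modification, contaminant flag) and per-sample
metadata (activity class, acquisition batch, fecal calprotectin in
µg/g). The gray-zone flag is the closed-interval test
`100 ≤ FC ≤ 250` and is always derived, never stored independently.
Active is the positive class everywhere.

## Synthetic cohort generator

The generator emulates the statistical structure of a quantified stool
DIA study; it does not simulate spectra, retention times or acquisition
windows.

Intensity model (log2 scale), for peptide *f* of protein *p* in sample
*s*:

```
x_fs = L_ps + o_f + e_fs
L_ps ~ N(b_p + d_p · 1[s Active], σ_prot²)
```

with protein baseline `b_p ~ N(20, 1.5²)`, fixed peptide offset
`o_f ~ N(0, 1²)`, peptide noise `e_fs ~ N(0, σ_pep²)`. The shared
latent `L_ps` gives peptides of one protein a population within-protein
correlation `σ_prot² / (σ_prot² + σ_pep²)` (0.8 at the defaults
σ_prot = 1, σ_pep = 0.5), mirroring the strong within-protein
co-variation real panels show. Defaults: 174 samples (66 Active / 108
Remission; 34 gray-zone split 21/13), four batches, 175 proteins with
2–6 peptides each (~700 peptides), and five informative proteins
carrying nine peptides at log2FC ≈ 1.8–2.5 — the composition and
effect-size range of the motivating cohort. The field does not pin
down variance components for stool peptidomics; a total null SD of
~1.1 log2 units is at the low-variability end of realistic for fecal
material and makes the planted effects strong but not separable.

Batch effects are applied afterwards as
`x → μ_f + δ_b (x − μ_f) + γ_b` — an additive offset plus a
multiplicative scale on the residual around the expected feature mean,
exactly the location/scale model the batch correction assumes. Batch
assignment is round-robin within each Activity × Gray cell, so batches
are technical, not confounded with class.

Dropout: each cell goes missing independently with probability
`1 − (1 − p_MNAR)(1 − p_MCAR)` where
`p_MNAR = logistic(−slope · (x − midpoint))` (defaults midpoint 16,
slope 1, MCAR 2%), giving the intensity-dependent censoring typical of
DIA. Gray-zone membership is assigned by configuration and the
calprotectin value then drawn uniformly in the matching interval; this
keeps subgroup composition exact, treating the observed composition as
fixed rather than modeled. What the generator does **not** emulate:
non-Gaussian intensity distributions, correlated (sample-level) dropout,
protein-abundance-dependent variance, shared-peptide (razor) ambiguity,
and real biological covariance between distinct proteins — passing
tests on synthetic cohorts therefore demonstrates the machinery, not
real-data effect sizes.

All randomness flows from one integer seed through named
`numpy.random.Generator` objects; no stage reads global random state.

## Preprocessing

Fixed order: log2 → contaminant filter → feature missingness filter →
sample missingness filter → quantile normalization → batch correction →
imputation. Two missingness thresholds coexist deliberately: the loose
sample filter (default 0.70) and the strict feature filter (default
0.30) that produces the compact peptide modeling matrix; both are
configuration parameters. Thresholds are strict (a feature missing in
exactly 30% of samples survives a 0.30 filter).

**Quantile normalization** uses the mean quantile function across
columns as the reference (for complete equal-length columns this is the
classic mean-of-sorted-columns). Columns with missing values are
mapped by rank interpolation onto the reference grid; ties receive the
mean of the reference values at their tied ranks. Missing cells stay
missing and within-column rank order is preserved.

**Batch correction** is a parametric empirical-Bayes location/scale
adjustment with an intercept-only design (no biological covariates are
protected, so it must only be applied to technical batches that are not
confounded with class). Per feature the data are standardized against
the batch-size-weighted grand mean and pooled variance (denominator
*n*); per-batch location γ̂ and scale δ̂² are shrunk toward batch-level
moments-matched priors (Normal for γ, inverse-gamma for δ²) by iterated
EB updates to a relative tolerance of 1e-4, then back-transformed. The
implementation is numerically interchangeable with the Bioconductor
reference (`sva::ComBat`, parametric prior) to ≤1e-6 on complete toys —
including its convergence-check idiosyncrasy of dividing by the signed
previous value. Extensions beyond the reference: missing entries are
tolerated (all moments computed on observed values) and features with a
fully-missing batch pass through uncorrected with a warning. The
non-parametric prior variant is not implemented. Note that EB shrinkage
removes the *systematic* batch shift; per-feature sampling noise in the
batch means legitimately remains after correction.

**Imputation** is feature-space kNN in the style of the classic
microarray imputer: a missing cell takes the mean of the k = 10 nearest
features (Euclidean distance over mutually observed samples, rescaled
by overlap; candidates must be observed at the target sample), with a
feature-mean fallback when no neighbor qualifies. The protein-level
matrix used for the volcano analysis is imputed; the peptide modeling
matrix relies primarily on the 30% missingness filter, with the same
kNN routine clearing residual missingness before model fitting.

**Protein rollup** for the differential stage is the per-sample mean of
each protein's observed peptide log2 intensities.

## Differential abundance

Per protein: Welch's unequal-variance *t*-test
(Active − Remission, two-sided, Welch–Satterthwaite df), BH step-up
adjustment, and volcano categories with strict thresholds: *up* iff
adj *p* < 0.05 **and** log2FC > 0.6; *down* symmetric; otherwise *ns*.
No moderated variance shrinkage — plain Welch tests are the intended
analysis.

## Stability-ensemble selection

Within each outer-training set, 10 class-stratified 80% subsamples are
drawn; the same subsample feeds all three selectors (making per-repeat
method comparisons meaningful and halving cost versus per-method draws):

* **Boruta** — per iteration, shuffled shadow copies of all undecided
  features join the design; a random forest (500 trees by default) is
  fit and a feature scores a hit when its Gini importance beats the best
  shadow. Hits are tested against Binomial(iters, ½), two-sided at
  p < 0.01 with Bonferroni correction over the features under test
  (without the correction ~1% of null features per run are falsely
  confirmed). Features still Tentative at `max_iter` count as not
  selected — the conservative reading.
* **L1 logistic (lasso)** — binomial deviance is profiled by stratified
  5-fold CV over a penalty path spanning λ_max (the smallest all-zero
  penalty) down to 0.01·λ_max when n < p (1e-4·λ_max otherwise), and
  the strongest penalty within one standard error of the deviance
  minimum is used (λ-1SE). Two details matter and are deliberate:
  (a) restricting the path — on near-separable data the deviance keeps
  improving into arbitrarily weak penalties, and an unrestricted
  "deviance-minimizing" choice stably retains a fringe of null features
  at 0.7–1.0 retention frequency, which would poison the consensus rule;
  (b) λ-1SE rather than λ-min, the sparse, stability-minded convention.
  With both, the selector is behaviorally identical to
  `glmnet::cv.glmnet(..., s = "lambda.1se")` on identical inputs.
  liblinear's penalized intercept is damped via `intercept_scaling=100`.
* **RFE-SVM** — iteratively fit a standardized linear SVM (C = 1), drop
  the lowest-|weight| half until each candidate subset size
  (default {5, 10, 20, 40}) is reached; the size with the best
  stratified 5-fold balanced accuracy wins (ties → smaller panel) and
  the elimination is replayed on the full data to that size.

Retention rule: per method, frequency = fraction of the 10 repeats
selecting the feature; the fold's stable panel is the union over
methods of features with frequency ≥ 0.7 (7/10 is in, 6/10 is out). A
pooled-frequency variant (one frequency over all 30 runs) is available
as a configuration switch but is not the default. The consensus panel
keeps features stable in ≥ 3 of the 5 outer folds; sub-threshold
features are reported with their fold counts so near-misses stay
visible.

## Nested cross-validation

Outer folds (k = 5) are stratified on the joint Activity × Gray cell by
proportional allocation: each cell's members are split `⌊n/k⌋` per fold
with remainders assigned to the currently smallest folds. This keeps
per-cell counts within ±1 of proportional *and* balances fold totals —
on the 174-sample composition the held-out folds come out
{35, 35, 35, 35, 34}. (A per-class stratifier that rounds cells
independently can produce a fold of 36, which is why the allocator is
hand-rolled.)

Per outer fold: selection (above) on the training split only → inner
stratified 5-fold grid search on the stable panel, maximizing mean
inner AUC with deterministic tie-breaks (balanced accuracy, then grid
order) → single refit on the full outer-training set → one-shot
prediction of the held-out fold. Hyperparameter grids: elastic net
mixing {0, 0.25, 0.5, 0.75, 1} × 20 log-spaced C in [1e-2, 1e2]; SVM
cost {0.1, 1, 10, 100}; radial kernel width by the median heuristic on
standardized inner-training data × {0.1, 1, 10}; naive Bayes smoothing
{1e-9, 1e-7, 1e-5}. SVM probabilities are Platt-style, calibrated on
training data only; the decision threshold is fixed at 0.5.

Reporting: per-fold Accuracy, Sensitivity (recall of Active),
Specificity (recall of Remission), F1 (on Active), balanced accuracy,
and AUC (Mann–Whitney with half-credit ties); mean ± sample SD (ddof=1)
across folds; pooled ROC and PR curves over the concatenated outer-test
predictions (PR-AUC as average precision); and a pooled gray-zone
evaluation computed once on the concatenated gray-zone outer-test
predictions rather than averaged over folds (per-fold gray counts are
too small for stable estimates).

Leakage discipline is structural: selection and tuning functions take
no test-data argument, and the suite verifies that replacing a held-out
fold's feature values with noise changes neither the selected panels
nor the chosen hyperparameters, fitted coefficients or inner metrics of
that fold's models.

## Interpretation

The post-hoc model is an elastic net refit on the full cohort
restricted to the consensus panel — a descriptive model, clearly not an
unbiased performance estimate. For linear models SHAP is exact and
closed-form under feature independence:
`φ_ij = β_j (x_ij − x̄_j)` on the log-odds scale, with base value equal
to the model output at the feature means (the conventional linear-SHAP
reference point); additivity `base + Σ_j φ_ij = logit(p_i)` holds to
numerical precision and is asserted at 1e-10. Panel redundancy is
summarized by pairwise Pearson correlation with average-linkage
clustering on the `1 − r` distance.

## Numerical and reproducibility choices

* Problem sizes in the test suite are scaled for a single-CPU run:
  panel-recovery checks use ~200 peptides × 174 samples with 60–100
  trees per forest and Boruta capped at 20–30 iterations; forest sizes
  are a speed/variance trade-off, not a statistical one, and defaults in
  the library remain at 500 trees / 100 iterations.
* Ties: tuning tie-breaks are documented and deterministic; RFE ranking
  ties break by column order (stable sort); AUC gives tied scores half
  credit.
* Degenerate inputs fail loudly: single-class labels, groups of < 2
  observations, batches of size 1, zero-variance features in the
  correlation panel, non-positive intensities under log2. A
  single-batch matrix passes through correction unchanged with a
  warning; Boruta Tentative maps to not-selected.
* Artifacts are written with 17-significant-digit floats; identical
  configuration + seed reproduces every file byte-for-byte.

## Known limitations

* The generator's Gaussian, homoscedastic intensity model and
  independent-cell dropout understate real DIA messiness; absolute
  performance numbers on synthetic cohorts are optimistic.
* Batch correction assumes batches are not confounded with class; the
  intercept-only design offers no protection if they are.
* The lasso path emulation matches the reference implementation's
  conventions but not its coordinate-descent solutions coefficient-for-
  coefficient; agreement is at the level of selected sets on tested
  data, not machine precision.
* Consensus-panel recovery depends on the chance correlation between
  null features and class labels in the realized cohort; with ~190 null
  peptides at n = 174, occasional single-peptide intrusions into the
  consensus are expected behavior of the rule, not a defect.
* No external-cohort validation logic, no classifier stacking, no
  protein-network or enrichment analysis; the consensus panel's protein
  annotation is exported for use with external services.
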