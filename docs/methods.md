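# Methods

## Pipeline overview

`logitda` predicts binary immunotherapy response (responder = RECIST
CR/PR) from bulk RNA-seq counts, with feature selection designed for the
covariate-shift setting: the model is trained on one cohort and deployed
on another whose per-gene distributions differ. The pipeline is

counts → DE prefilter → name filter → BW-ratio top-p → KS domain-adaptation
filter → per-cohort standardization → penalized logistic regression, with
(p, α_DA, λ) tuned jointly by repeated stratified cross-validation.

## Normalization and standardization

Counts are converted to log2(TPM+1): per sample, `rate_g = count_g /
length_g(kb)`, `TPM_g = 1e6 · rate_g / Σ rate`, so each sample's TPM sums
to 1e6 before the log. Gene lengths come from a user-supplied two-column
TSV (the simulator emits one); transcript-level quantification is out of
scope.

Each cohort is standardized separately ("ST"): every gene is scaled to
mean 0, variance 1 (n−1 denominator) *within its own cohort*. This removes
cohort-level location/scale differences and is justified when the
responder fraction is similar across cohorts — it would distort scores if
prevalences differed sharply. Zero-variance genes are dropped with a
warning. Single new samples cannot be cohort-standardized; they are scored
with the frozen training moments stored in the model
(`apply_standardization`), and model metadata labels which mode produced a
score. BW-ratio ranking is invariant to per-gene affine rescaling, so
standardization affects only classifier fitting, not selection order.

## Differential-expression stage

The built-in test is deliberately lightweight: median-of-ratios size
factors (reference genes = all-positive rows, factors scaled to geometric
mean 1), per-class means on normalized counts, a pooled per-gene
method-of-moments dispersion for Var = μ + φμ² (floored at 1e-8, no
shrinkage), and a Wald test on the log mean ratio with delta-method
standard errors; a pseudocount of 0.5 on class means keeps fold changes
finite. A Welch t-test on log2(normalized+1) is available as a model-free
fallback. Type-I error is calibrated on simulated null cohorts
(empirically ≈0.03–0.07 at nominal 0.05, n = 100). The stage is pluggable:
an externally computed DE table (gene, log2fc, pvalue, padj — e.g. from a
shrinkage-based DE package) can replace the built-in test, since the
pipeline consumes only the surviving gene list. Genes pass at BH-adjusted
p strictly below the threshold (default 0.10). DE always runs on raw
counts, never on standardized values.

## Domain-adaptation filter

The DA stage is unsupervised: for each candidate gene the two-sample KS
statistic D is computed between the training and test cohorts'
log2(TPM+1) values, and genes with D > α_DA are discarded. Smaller α_DA is
stricter; the grid spans 0.2–0.8. **Scale choice:** D is computed on
log2(TPM+1) *without* per-gene standardization. Standardizing each gene
within each cohort first would erase exactly the location/scale
differences the filter exists to detect (leaving D at its sampling-noise
floor, ≈0.19 at n = 100 per cohort), so the filter operates upstream of
ST. At 2,000 genes and n = 100/cohort, a 2-SD location shift is detected
in ~100% of shifted genes at α_DA = 0.2 while ~6% of unshifted genes are
lost — the compositional coupling of TPM means heavily shifted
transcriptomes inflate D slightly for all genes, which is why the filter
is applied after the top-p stage rather than genome-wide.

Test-cohort **labels** are never read at any selection or training stage;
only the test expression matrix enters, and only through D. With the DA
stage disabled (ablation mode) the test cohort has no influence at all.

## Classifier and model selection

The fit minimizes `(1/n) Σ log(1+exp(−ỹ(β₀+xβ))) + λR(β)` with ỹ ∈ {−1,+1},
R = ‖β‖₂² (ridge, default) or ‖β‖₁ (lasso), intercept unpenalized (with
~23% responders, penalizing it would bias probabilities). Fits delegate to
scikit-learn with the exact objective mapping C = 1/(2nλ) (ridge) or
1/(nλ) (lasso), tolerance 1e-10; the ridge objective is strictly convex so
the solution is unique (verified against independent numeric optimizers).

Cross-validation: seeded repeated stratified k-fold (default k = 5;
k = n gives leave-one-out, where repeats collapse to 1 because the folds
are deterministic). Per repeat, out-of-fold probabilities are pooled and
scored once — pooling is more stable than per-fold AUC when a fold holds
only a handful of responders. Mean and SE over repeats are reported per λ;
ties prefer the larger λ. The joint grid search evaluates each (p, α_DA)
selection (computed once on the full training cohort, with the DE/BW/KS
stage outputs cached and shared across grid points), tunes λ by CV, picks
the triple with the best mean AUC (ties → smaller p, then larger λ), and
refits on all training samples.

Because selection sees the training labels before CV, the reported CV AUC
is optimistically biased — this mirrors the protocol the method was
defined with. The honest variant (`nested=True`) reselects features inside
every training fold (DA still references the external test cohort, which
carries no labels) and re-standardizes per fold; it is slower and reports
lower, unbiased CV AUC.

Default λ grid: 30 points log-spaced in [1e-3, 10], chosen to bracket the
ridge optima typically selected on cohort-scale data (≈0.04–1.1). Default
p grid: {15, 20, …, 200} ∪ {210, 220, …, 500}.

## Evaluation and signature benchmarking

AUC uses the Mann–Whitney formulation (ties count 1/2), which equals
trapezoidal ROC integration. Confusion counts threshold predicted
probability at 0.5 by default, with `score ≥ threshold` counted positive;
the threshold is exposed because no canonical rule exists for it.

Fixed published signatures are benchmarked under the same harness:
per-cohort ST, λ by repeated CV on the training cohort, refit, evaluate on
the test cohort. Genes absent from either cohort (or zero-variance) are
dropped and recorded — never imputed. Signature integration is set union,
first signature's order preserved, shared genes counted once. Only the
8-gene T-effector and 5-gene CD8 T-cell panels are bundled; other panels
are registered by citation and must be supplied by the user. Score
distributions across CR/PR, SD and PD groups are compared by two-sided
Mann–Whitney tests (exact for group sizes ≤ 20, normal approximation with
tie correction otherwise).

## Prognostic screen

Each screened gene dichotomizes the cohort at its expression median
(interpolated for even n; value ≥ median = "high"), the groups are
compared by the standard log-rank test (lifelines), and BH adjustment runs
across exactly the screened gene set. Direction (high_better/low_better)
is read from the Kaplan–Meier curves at median follow-up, since the
log-rank statistic is unsigned. Event/censoring ties at the same time
follow the usual convention (events first).

## Synthetic cohorts

The generator draws NB counts (Var = μ + φμ², per-gene φ ~ Gamma with mean
0.2), per-gene baseline log2 means uniform in [3, 10], lognormal per-sample
depth factors (σ = 0.2) so size-factor estimation is exercised, responder
labels Bernoulli(prevalence = 0.23 — the responder fraction of a
~300-patient checkpoint-inhibitor trial), and informative genes whose
log2 mean shifts by a signed effect in [0.5, 1.5] in responders.

**Domain-shift semantics.** A shifted gene is *non-transferable*: in the
test cohort its log-mean is displaced by `shift_location` (default 2) SDs
of its log2 expression, and its response association (if informative) is
absent. The displacement is the marker the KS filter detects; the broken
association is what makes the gene worthless to a transferred classifier.
A displacement alone would be erased by per-cohort standardization and
could neither hurt a model nor reward the filter, so it would not exercise
the method. Consequently, passing the ablation benchmark shows the filter
removes *marked* non-transferable features; on real data, shift magnitude
and association breakage need not coincide so cleanly.

**Survival.** Times are exponential with hazard `(ln2/median_OS) ·
HR^(z̄/1.596)`, where z̄ is the mean z-score of the survival genes' log2
expression and 1.596 = 2√(2/π) is the expected z-gap across a median
split — so `survival_hr` is, by construction, the hazard ratio realized
across a median split of a single survival gene (verified: 1.93 realized
at configured 2.0, n = 500). Censoring is administrative at the empirical
(1 − censor_rate) quantile. With several survival genes the per-gene split
is diluted by √k.

What the generator does **not** model: gene–gene correlation, batch
structure within a cohort, library-composition extremes, non-NB zero
inflation, informative censoring. Passing tests therefore demonstrates
correctness of the machinery and its behavior under the stated mechanisms,
not clinical performance.

## Benchmark scenarios and problem sizes

The packaged study conditions, used by the test suite and
`scripts/acceptance.py`:

- *Null calibration*: no informative/shifted/survival genes; 500 genes ×
  100 samples (DE), 30 noise features × 100 samples averaged over 10
  replicate datasets (CV — a single n = 100 dataset carries ≈0.08 AUC
  sampling noise), 20 screens of 49 genes × 100 samples (survival).
- *Signal recovery* (`signal_config`): 2,000 genes, 40 transferable + 40
  non-transferable informative genes, cohorts 150/80, α_DA = 0.2, p = 150.
- *Ablation* (`shifted_ablation_config`): 600 genes, cohorts 100/120, 24
  informative genes of which 18 are non-transferable, effects 0.5–0.9
  log2 units, dispersion 0.3 — sized so neither model saturates and the
  DA benefit is visible; grids are reduced (p ∈ {20, 40}, α_DA ∈ {0.2, 0.4},
  5 λ points, 3 CV repeats) since the contrast, not the tuning resolution,
  is under test. Across 20 replicates the DA model wins ~19–20/20 with a
  mean held-out AUC gain of ≈0.16.

## Numerical conventions

Deterministic tie-breaks throughout: BW ranking ties → ascending gene id;
CV λ ties → larger λ; grid ties → smaller p then larger λ. All stochastic
procedures (simulation, fold assignment) are reproducible bit-for-bit from
their seed. BW-ratio returns +inf when within-SS = 0 with between-SS > 0
(ranks first) and 0 for the 0/0 case. KS uses exact ECDF evaluation — the
statistic, not its p-value, is thresholded, so no asymptotic approximation
enters. BH adjustment enforces monotonicity and caps at 1.

## Known limitations

- The per-gene MoM dispersion is noisy at small n and unshrunk; the DE
  stage is a screen, not an inference engine — import a dedicated DE
  table when inference quality matters.
- The default (non-nested) CV AUC is optimistic by construction; use
  `nested=True` for honest estimates.
- Per-cohort ST assumes comparable outcome prevalence between cohorts.
- The DA filter tests marginal distributions only; a gene can match
  marginally while its joint relationship with response changes.
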