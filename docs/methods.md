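# Methods

## The synthetic cohort generator

Clinical warfarin cohorts carry genotype and medication data that cannot be
shared, so the package operates on synthetic cohorts designed to emulate the
published summary statistics of a 641-patient southern-Chinese heart-valve
cohort.

**Marginals.** Continuous variables are truncated normals — age 46.6 (10.9)
years on [18, 90], height 160.6 (8.1) cm on [130, 200], weight 56.4 (9.3) kg
on [30, 120]; the truncation bounds are physiologic, fixed in the config so
tests are stable. Binary flags are independent Bernoulli draws at the
published prevalences (male 0.404, smoking 0.105, mechanical valve
replacement 0.789, atrial fibrillation 0.323, …), with one structural
exception: bioprosthetic valve replacement is the complement of mechanical
valve replacement, because every patient in the emulated cohort underwent
exactly one of the two. Genotypes are categorical draws — CYP2C9
(*1/*1, *1/*3, *3/*3) at (0.908, 0.087, 0.005) and VKORC1 (CC, TC, TT) at
(0.010, 0.190, 0.800) — encoded ordinally by variant-allele count, which
matches the monotone dose decrease per allele; one-hot encoding is available
as a feature-frame switch.

**Dose model.** The stable dose is

```
dose = clip( intercept + Σ_v β_v (x_v − c_v)
             + γ · (age − 45)/10 · T + δ · (√weight − √56), 0.5, 10 ) · exp(ε)
```

with `T` the VKORC1 T-allele count and `ε ~ N(0, σ)`. Defaults: intercept
5.0 mg/day (the dose of a reference wild-type patient), −0.90 mg/day per
VKORC1 T allele and per CYP2C9 *3 allele, −0.020 per year of age above 45,
+0.40 for smoking, smaller terms for surgeries, comorbidities and
co-medications (each variant allele and a severe-embolism history lower the
dose; smoking raises it, consistent with increased warfarin clearance).
γ = −0.15 and δ = 0.60 are the two deliberately nonlinear terms — an
age-by-genotype interaction and a saturating weight effect — present so that
linear and nonlinear learners genuinely differ, which is the regime stacking
heterogeneous learners is meant for. σ = 0.12 of multiplicative lognormal
noise yields an irreducible holdout RMSE around 0.43 mg/day at the typical
3.6 mg/day dose. The noise is multiplicative (not additive) so doses stay
positive and the noise scale tracks the dose scale; with σ = 0 the map is
deterministic and the stored dose is exactly recomputable from the stored
covariates.

**What the generator does not emulate:** missing data (records are complete
by construction; the CSV reader rejects missing cells), correlations among
covariates beyond the valve-type complement (real age/weight/comorbidity
dependence is richer), INR trajectories, and any site or batch structure.
Passing tests therefore demonstrate that the pipeline's machinery —
splitting, auditing, selection, stacking, scoring — behaves correctly under
known ground truth, not that the default coefficients are clinically
calibrated.

## Split auditing and the exclusion rule

The split is simple random (test size = ⌊fraction·n⌋), with balance
verified post hoc rather than enforced by stratification. Continuous
variables are compared by a Welch two-sample t-test (a binned χ² variant is
available behind a flag), binary flags by Fisher's exact test on the 2×2
train/test × present/absent table, and 3-level genotypes by a
Fisher–Freeman–Halton-style exact test: full enumeration of all tables with
the observed margins when the grand total is ≤ 200, otherwise Monte Carlo
under the multivariate-hypergeometric null with a fixed seed (20 000 draws;
the add-one p-value estimator keeps p > 0). Cells with no variation are
reported as non-computable rather than silently dropped.

A binary flag is excluded from model training when its total event count is
below `min_events` (default 5) or the test partition holds zero positives;
with so few events the exact test says nothing about balance and the flag
mainly encodes which partition its rare carriers landed in. Excluded flags
remain available to the correlation analysis, which has no train/test
boundary to leak across. Continuous and ordinal variables are never excluded
by this rule.

## Correlation ranking

Pearson's r, Spearman's rho (Pearson on midranks) and Kendall's tau-b (the
tie-corrected denominator √((n₀−T_x)(n₀−T_y))) are computed per variable
against dose and aggregated as the arithmetic mean of their absolute values.
Binary flags enter as 0/1 numerics, making the Pearson entry the
point-biserial coefficient. p-values (t approximation for r and rho, normal
approximation for tau-b) are reported but play no role in the ranking.
Constant variables are routed to an exclusion list with a reason.

## Feature and learner search

The same bidirectional engine serves both searches. A forward search grows
a set from empty, offering candidates in descending priority (Gini
importance for features; single-learner stack CV performance for learners)
and accepting an addition when the CV RMSE strictly improves. A backward
search shrinks a set from the full pool, removing the lowest-priority
candidates when the score does not worsen (ties resolve toward the smaller
set, tolerance 1e-12). Three lock rules bind them: forward-added items are
never removed, backward-removed items are never re-added, and the search
stops when both sides hold the same set. If neither side can move and they
still disagree, the better-scoring endpoint wins (ties prefer the smaller
set, then lexicographic order); the pass count is capped at 2·|pool|.
Subset scores are cached, so no subset is evaluated twice.

The wrapper evaluator is the pooled out-of-fold RMSE of a 100-tree random
forest under 5 shared, seeded folds; the empty feature set is scored by the
fold-mean predictor so the first addition must beat an intercept-only
baseline. Because acceptance is strict improvement of a cross-validated
score, a pure-noise covariate slips in when it improves CV RMSE by chance —
roughly one seed in ten in our simulations. That risk is inherent to
cross-validated wrapper search; we deliberately did not add an improvement
margin, which would bias the search away from the exhaustive-enumeration
optimum it otherwise recovers essentially always on small pools.

RFECV is an explicit elimination loop (drop the `step` least-important
features per round, score every visited feature count by CV RMSE, return
the count minimising it, ties to fewer features) rather than the
scikit-learn class, to control the scorer, tie-break and trace; scikit-learn
supplies the estimators and folds. The correlation filter keeps variables
with mean |correlation| ≥ threshold (default 0.10) or the top-k.

## Stacking

The learner pool and its fixed hyperparameters: RF (100 trees), GBRT (100
stages, learning rate 0.1), GPR (RBF kernel, observation noise 1e-10,
normalized target), SGD (squared error, L2, α = 1e-4), KRR (linear kernel,
α = 1), Bayesian ridge, MLR, SVR (RBF, C = 1, ε = 0.1); the meta-learner is
the RBF SVR. Features are standardized (train-fitted scaler) before the
kernel and gradient learners — GPR, SVR, SGD, KRR, Bayesian ridge — and left
raw for the tree ensembles and MLR. Kernel ridge has no intercept, so KRR
additionally regresses on a standardized target and back-transforms;
without this its predictions sit near zero dose.

Blending is **per learner**: each learner's K fold models are collapsed into
that learner's single test column, so the meta-learner sees the same matrix
width at train (out-of-fold Z) and test (blended Z*) time. Inverse-RMSE
weights require strictly positive fold RMSEs; a perfect fold model is a
degenerate case the API redirects to arithmetic blending. Fold bookkeeping
(per-fold train/validation index sets) is stored on the stacked dataset and
checked: any fold model whose training rows intersect its validation rows,
or validation folds that fail to partition the training set, raise
immediately.

The learner search scores a candidate subset by the 5-fold CV RMSE of the
meta-learner on the corresponding Z columns. Z is already out-of-fold, so
base-level optimism is removed without re-fitting the base pool per
candidate — re-fitting would multiply cost by the pool size for no change
in the ranking. Single-cohort differences between the three variants are
small relative to holdout sampling noise (a 60-patient holdout), which is
why the variant comparison is stated as a median over ≥ 20 seeded cohorts.

**Pipeline order** (leakage control): (1) reserve the 10% holdout;
(2) audit the split and apply the exclusion rule; (3) feature selection on
the 90% only; (4) stacked dataset and learner search inside the 90%;
(5) score the untouched holdout. All stage seeds derive from one top-level
seed via a seed sequence and are recorded in the result JSON, which makes a
rerun byte-identical.

## Numerical and scale choices

* ERR±20% uses the actual dose in the denominator and an inclusive band
  (|ŷ−y|/y ≤ 0.20); actual doses must be positive.
* Dose bands close the published open boundaries into the moderate band
  (2 and 4 mg/day are moderate) so the partition is exhaustive.
* CSV I/O is UTF-8, dot-decimal, snake_case headers, target column
  `dose_mg_day`; reads use round-trip float parsing so write∘read is the
  identity.
* Problem sizes in the shipped tests and acceptance script — 20 cohorts of
  n = 600 for the variant ordering, 100 toy datasets for the
  search-vs-brute-force checks, 5 cohorts for the acceptance medians — were
  chosen to give stable medians and match rates at desk scale; all are
  parameters, not constants.

## Known limitations

Independent covariates make the selection problem easier than in real
cohorts (no collinearity traps beyond the engineered valve-type complement
and duplicated-feature tests). The Monte-Carlo exact test p-values are
estimates with ~1/√20000 resolution. The heuristic search optimises CV RMSE
only; on a near-linear cohort it can select a subset that is CV-optimal but
not holdout-optimal for a given seed — the documented behaviour of any
cross-validated model selector.
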