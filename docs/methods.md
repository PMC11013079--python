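# Methods

`bascox` implements a complete survival-metabolomics workflow: a weighted
bile-acid risk score for patients with acute coronary syndrome (ACS), built
by stability-selected elastic-net Cox regression and evaluated against two
right-censored endpoints — a composite cardiovascular endpoint (MACE:
myocardial infarction, heart-failure hospitalization, or all-cause death)
and all-cause death itself. Because the motivating cohort is private, the
package ships a calibrated synthetic cohort generator with known ground
truth; every statistical claim the test suite makes is a claim about
recovery of that truth.

## The model

For subject *i* with covariate row `x_i`, the Cox proportional-hazards model
sets `h_i(t) = h_0(t) exp(x_i' beta)`. Coefficients are estimated by
maximizing the log partial likelihood; both the Breslow and the Efron tie
corrections are implemented with analytic gradients and Hessians
(`bascox.cox.neg_log_partial_likelihood`). Unpenalized fits
(`CoxPH(...).fit()`) use Newton–Raphson with step-halving, stopping at
max |score| < 1e-9 or a relative log-likelihood change < 1e-10; Wald
standard errors come from the inverse observed information. Monotone
likelihood (separation) is detected by coefficient escape (|beta| > 20) and
reported as a flagged, non-converged result rather than a silent estimate.

The penalized estimator (`CoxElasticNet`) minimizes

    (1/n) * (-log PL(beta))  +  lambda * [ alpha * ||beta||_1
                                           + (1 - alpha)/2 * ||beta||_2^2 ]

by cyclic coordinate descent on an iteratively reweighted quadratic
approximation with soft-thresholding, warm-started along a decreasing
log-spaced lambda path anchored at `lambda_max` (the smallest lambda with an
all-zero solution, computed from the null-model score). This is the
glmnet-style parameterization; lambda values quoted under other scalings do
not transfer. Internal standardization of columns is on by default and
coefficients are returned on the original scale. Exit is verified against
the subgradient (KKT) conditions at tolerance 1e-7; during development the
coefficient paths were confirmed to match R `glmnet` to ~2e-6 and the
cross-validation deviance to match `cv.glmnet` to five decimals on shared
folds (the shipped tests use a generic bound-constrained optimizer and an
unpenalized Newton fit as independent oracles instead).

Ties default to Breslow inside the penalized solver (matching glmnet) and to
Efron for the unpenalized models; the original analysis does not state its
choice, so both are available everywhere.

## The pipeline

1. **Missingness filter** — metabolite columns with more than 20% missing
   cells are dropped (by default this removes TUDCA, whose simulated
   missingness sits at 25%).
2. **Imputation** — remaining metabolite gaps are filled by iterative
   round-robin (chained) regression on the other metabolites only (never on
   outcomes), modeled on the log scale. The default per-column learner is
   Bayesian ridge: on a jointly log-normal panel the linear model is the
   correct model class, and at n ≈ 300 it was the only learner whose
   imputation error reliably beat the mean-imputation baseline; a
   missForest-style extremely-randomized-trees learner (60 trees, leaf size
   15) and a kNN learner are selectable. Imputation error is scored on the
   log scale: on the raw scale, back-transformed conditional medians are
   penalized against the skew-inflated column mean regardless of learner.
   BMI gaps (the only covariate allowed to be incomplete) are filled by
   chained equations over the clinical covariates. Single imputation is
   used; the downstream analysis consumes one completed dataset.
3. **Inverse normal transformation (INT)** — every metabolite is mapped to
   `Phi^{-1}((r - c) / (n - 2c + 1))` of its (average, for ties) rank, with
   the Blom offset c = 3/8 by default (offsets 0, 1/3, 3/8, 1/2 are
   available). Downstream hazard ratios are therefore per 1 SD. Blom scores
   have SD slightly below 1 at finite n (about 0.98 at n = 309); exact unit
   SD is not promised and not asserted.
4. **Univariate screen** — per metabolite, a crude Cox model and a
   multivariable model adjusted for 17 clinical confounders, with
   Benjamini–Hochberg q-values computed across the 15 metabolites within
   each model family separately (crude/adjusted × endpoint; the family
   structure is a package choice, the source analysis does not state one).
5. **Tuning** — 80/20 random split; for each alpha in 0.10..1.00 (step 0.05)
   lambda is chosen by 10-fold cross-validated partial-likelihood deviance
   on the training set (event-stratified folds, shared across alphas, the
   robust "difference" form `2[nll_train(beta) - nll_train\fold(beta)]`);
   each (alpha, lambda(alpha)) refit is scored by Harrell's C-index on the
   held-out test set and the best pair wins. The C-index depends only on
   risk orderings, so exact ties across alphas are common; ties break toward
   the smaller alpha — the denser, more ridge-like model that the elastic
   net's grouping rationale favors on collinear panels.
6. **Stability loop** — the tuned (alpha*, lambda*) is refit on 100 fresh
   random 80% subsamples; metabolites with nonzero coefficients in **all
   100** fits form the consistent set.
7. **Score** — each member's weight is the mean of its 100 coefficient draws
   (zeros included; 95% CI = 2.5/97.5 percentiles of the draws); the
   per-subject weighted sum is z-standardized on the full cohort (n−1 SD)
   and its crude and 17-confounder-adjusted Cox HRs per 1 SD are the
   pipeline's endpoint. The standardized score is invariant to rescaling
   all weights, so only the weight *pattern* matters.

The 17-column confounder design is age, sex, BMI, smoking (two dummies:
former, current; never as reference), hypertension, dyslipidemia, type 2
diabetes, discharge diagnosis (two dummies: STEMI, NSTEMI; unstable angina
as reference), statins, beta-blockers, aspirin, diuretics, oral
antidiabetics, insulin, and eGFR. Entering all three exhaustive diagnosis
dummies would make an intercept-free Cox design rank-deficient, hence the
reference-coded version.

## The synthetic cohort generator

`bascox.simulate` draws cohorts that emulate a 309-patient ACS study
followed ~10 years with no dropout (administrative censoring only):

- **Covariates** follow the published baseline table: age 64.9 ± 12.3,
  71.2% men, BMI 28.1 ± 4.0, smoking 35.6/33.9/30.4%, diagnosis
  UA/STEMI/NSTEMI 15.9/22.0/62.0%, T2D 37.2%, hypertension 67.6%,
  dyslipidemia 60.8%, the six medication prevalences, and eGFR declining
  with age (median ≈ 81). Glucose-lowering drugs are drawn conditionally on
  diabetes so the marginals hold while the dependence is realistic.
- **Bile acids** (16 analytes) are jointly log-normal. The correlation is a
  factor model — one global factor (loading 0.30) plus one factor per
  conjugation family (loading 0.45) — giving within-family r ≈ 0.29 and
  cross-family r ≈ 0.09, PSD by construction. Log-scale SD is 0.9
  throughout.
- **Events** come from exponential proportional-hazards clocks for latent
  MI, HF and death; MACE is their minimum, so death implies MACE and
  `time_mace <= time_death` by construction. The metabolite part of each
  linear predictor applies to the latent standard-normal metabolite matrix —
  the population analogue of the INT values. A single-process composite
  (one clock carrying the whole MACE hazard, exactly PH) is available via
  `composite_mode="single"` for effect-recovery experiments.
- **Ground truth**: ten metabolites carry MACE effects with the reported
  sign pattern (DCA, CDCA, GCA, GUDCA positive; CA, TDCA, GCDCA, HDCA,
  UDCA, LCA negative) at equal magnitude 0.1693 per SD; four carry death
  effects (DCA, GCA positive; CA, HDCA negative) at equal magnitude 0.1489
  per SD. Magnitudes and baseline rates (0.0111/y MI, 0.0089/y HF,
  0.0289/y death) were calibrated once by large-n (60,000) simulation so
  that (a) the confounder-adjusted HR per 1 SD of the true standardized
  score is ≈ 1.35 for MACE and ≈ 1.31 for death, and (b) a 309-subject
  cohort averages ≈ 131 MACE and ≈ 90 deaths over 10 years. An earlier
  factor structure with stronger loadings was rejected during development
  because, combined with the opposite-sign pattern inside families, it
  cancelled the marginal effects of the positive-truth metabolites almost
  exactly — an emulation artifact that would have made the panel's signal
  undetectable by any method.
- **Missingness** is MCAR by default at fixed per-metabolite rates (TUDCA
  0.25; the other fifteen average ≈ 1.9%, max 8.7%), with an optional
  age-dependent MAR mechanism; BMI is blanked at 2%. Original values are
  kept in a hidden truth block for imputation-error scoring.

What the generator does **not** emulate: metabolite–covariate confounding
(bile acids are drawn independent of the clinical covariates, so crude and
adjusted score HRs coincide in truth), competing-risk structure beyond
composite dominance, LC-MS assay artifacts (batch effects, detection
limits), and non-PH effects. Passing recovery tests therefore demonstrates
the statistical machinery, not robustness to those real-data features.

## Known limitations of the procedure (measured, not hidden)

The test suite asserts the nominal recovery properties at the calibrated
study conditions, and several of them fail **by design of the procedure**,
not of the implementation (the solver matches independent oracles to 1e-6):

- *Consistent-set recovery.* With the true score HR fixed at 1.35, each of
  the ten true metabolites carries only ≈ 0.17 log-HR per SD (univariate
  z ≈ 1–2 at n = 309). "Nonzero in 100 of 100 overlapping 80% subsamples"
  is then an unreliable classifier: weak true effects drop out of at least
  one subsample unless lambda is very small, while at such lambdas
  correlated null metabolites ride cohort-level noise into all 100 fits.
  Sweeping (alpha, lambda) exhaustively per cohort never reached 8/10 true
  with zero nulls in ten cohorts; the tuned pipeline achieves a median
  consistent set of ~0–3 members.
- *Score optimism.* Selection, weighting and association all reuse the one
  cohort, so constructed scores are optimistically associated with the
  outcome — under a fully null generator a constructed score's crude CI
  essentially never covers HR = 1. The same circularity affects the
  original analysis design.
- *Tuning noise.* The cross-alpha winner is picked by a C-index on 61 test
  subjects; on null data the maximum over 19 alphas finds spurious signal
  in roughly a third of replicates.

## Numerical and operational choices

- Coordinate-descent tolerances: inner beta-change 1e-10, KKT check 1e-7,
  10,000 sweep cap, IRLS cap 50 (200 on one tighter retry); coefficients
  with |beta| < 1e-10 are snapped to exact zero (soft-threshold boundary
  roundoff).
- Lambda path: 30 values, ratio 0.01, log-spaced — glmnet-like defaults
  sized to the 15-metabolite panel.
- Stability iterations that fail to converge are re-drawn with a fresh
  seed (logged); more than 10 consecutive failures abort.
- Every stochastic stage takes an explicit seed; a full `run_pipeline`
  under one config is reproducible byte-for-byte, including the report
  fingerprint (SHA-256 of the canonical JSON).
- Default problem sizes in tests and the acceptance script (n = 309
  cohorts; 100-replicate batteries for recovery and coverage; 10/5
  replicates per endpoint in the script) are the package's own choices,
  matching the emulated study's scale while keeping simulation batteries
  comfortably re-runnable.
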