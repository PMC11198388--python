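# Methods

`survstrat` implements a survival-tree risk-stratification workflow for
heart-failure cohorts with severe secondary mitral regurgitation (sMR),
together with a calibrated synthetic cohort generator that makes the whole
workflow testable without patient-level data. This note records the models,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic studies do and do not demonstrate.

## The statistical workflow

The analysis takes a patient-level table (follow-up time in years, death
indicator, inclusion year, HF subtype, and covariates tagged as clinical,
echocardiographic or laboratory) and proceeds in five stages.

**1. Stratified derivation/validation split.** 70% of patients are drawn
without replacement into a derivation cohort, stratified by HF subtype
(HFpEF / HFmrEF / HFrEF), with per-stratum ceiling rounding:
`ceil(0.7 · n_stratum)`. Ceiling rounding is the unique simple convention
under which strata of 331/330/656 patients yield a 923/394 split, which is
the published arithmetic this stage must reproduce.

**2. Univariate Cox screen.** Every covariate is fitted alone in a Cox
proportional-hazards model; per-unit hazard ratios (and per-SD for
continuous covariates), Wald 95% CIs and p-values are tabulated. Fits that
fail (constant covariate, monotone likelihood) are flagged rows, not
aborts.

**3. Bootstrap stepwise stability selection.** Within each variable domain
(clinical, echo, lab) separately: B = 500 bootstrap resamples of the
derivation cohort (same n, with replacement) are drawn; on each, a
forward/backward stepwise Cox procedure runs with Wald-p entry/removal
thresholds p_enter = 0.05, p_remove = 0.10; a covariate is retained when
its inclusion frequency is ≥ 85%. The union of the three retained sets
feeds the tree. The p-value stepwise rule with (0.05, 0.10) is the
conventional default; an information-criterion rule was considered and not
adopted because the stepwise criterion in the original procedure is not
recoverable. Note that the naive bootstrap makes stepwise p-values
anticonservative (duplicated patients roughly double the apparent
information), which inflates null-covariate inclusion frequencies into the
0.3–0.8 range — the harsh 85% threshold is what makes the procedure
selective despite that.

**4. Conditional-inference survival tree.** Recursive partitioning in the
permutation framework of Strasser and Weber:

* At each node, per-subject log-rank scores are recomputed from the node's
  own survival data: `a_i = δ_i − Λ̂(t_i)`, the event indicator minus the
  Nelson-Aalen cumulative hazard at the subject's time. The at-risk set at
  time t is `{i : t_i ≥ t}` (events precede censorings), under which the
  scores sum to zero identically.
* Each candidate covariate g is tested for association with the scores via
  the linear statistic `T = Σ g_i a_i` standardised by its exact
  permutation-null moments: `E[T] = (Σ g_i) ā`,
  `Var[T] = n/(n−1) · V_a · (Σ g² − (Σg)²/n)`. Numeric covariates use the
  two-sided normal reference; categorical covariates (≤ 5 levels) are
  one-hot coded and use the quadratic form with a pseudo-inverted
  covariance (relative tolerance 1e-8) against a chi-squared reference with
  df = rank. The quadratic-form statistic (rather than a maximum-type one)
  matches the common reference implementation of this framework.
* The smallest p across the m testable candidates is Bonferroni-adjusted
  (`p_adj = min(1, m·p_min)`); the node becomes a leaf if `p_adj ≥ α`
  (α = 0.05).
* The cutpoint of the selected covariate maximises |z| of the two-sample
  linear statistic over observed values, subject to both children having at
  least `minbucket` patients; ties go to the smallest threshold; the split
  convention is `value ≤ threshold → left`. Categorical covariates use
  exhaustive binary level partitions.
* Stopping: adjusted significance, node smaller than `minsplit`
  (= 2·minbucket by default), no admissible cutpoint, an all-censored node,
  or an optional depth cap. Defaults: minbucket = 95 (the published
  minimum subgroup size), α = 0.05.
* Leaves are numbered left to right. No surrogate splits; complete cases
  are required at fit time. Degenerate tests (constant scores or covariate
  within a node) return p = 1 rather than dividing by zero.

For small n (≤ 10) an exact enumeration of the permutation distribution is
available as a verification oracle; the asymptotic p-value tracks the exact
one within ~0.15 absolute at n ≤ 8, with identical ordering — the
asymptotic path is used for all real work.

**5. Subgroup reporting and validation.** Patients are routed through the
fitted (frozen) tree; per subgroup, Kaplan-Meier survival at 1 and 6 years
and a Cox hazard ratio against the reference subgroup are reported. The
reference is the leaf with the highest Kaplan-Meier survival at the 6-year
landmark (falling back to the largest follow-up common to all leaves). The
validation cohort is routed through the derivation-fitted tree without
refitting; temporal validation pools patients into two cohorts by
alternating sorted inclusion years (the alternating-patient variant is
available via `temporal_split` on a re-sorted frame but the calendar-year
reading is the default). Per-subtype sub-analyses repeat selection + tree
on each subtype subset without an internal split, with the minimum leaf
size scaled to the subtype's share of the cohort (floor 30) unless
overridden.

## Survival estimators

Nelson-Aalen, Kaplan-Meier (with Greenwood variance) and Cox regression are
implemented directly on sorted arrays. The Cox partial likelihood supports
Efron (default) and Breslow tie corrections; Efron is the more accurate
standard choice and the two agree to < 1e-8 when no ties exist. Newton
iteration starts at β = 0, halves steps when the likelihood decreases, and
stops when the max-norm of the gradient falls below 1e-9 scaled by the
likelihood magnitude (an absolute 1e-9 is unreachable in double precision
for cohorts of tens of thousands) or the Newton step collapses below
1e-10. Covariates are centred internally for exponential stability.
Standard errors come from the inverse observed information; CIs and
p-values are Wald. A monotone (separated) likelihood is reported as an
error naming the offending covariate; detection is non-convergence in 50
iterations or |β| > 20 — on the covariate scales this package works with, a
log hazard ratio above 20 is never a finite estimate. Fits agree with R's
`survival::coxph` (eps = 1e-14) to ~1e-11 and with lifelines to that
package's own ~1e-5 convergence.

## The synthetic cohort generator

No patient data accompany the published analysis, so the generator emulates
the study population:

* **Marginals** (Table-style summaries): continuous covariates are normal
  when the printed IQR is roughly symmetric about the median, lognormal for
  right-skewed biomarkers (NT-proBNP, BUN, creatinine, bilirubin, WBC,
  AST); the scale is (q3 − q1)/1.349 on the modelled scale. Binaries use
  printed prevalences; LV dysfunction grade and tricuspid-regurgitation
  style categoricals use printed level frequencies. Covariates are sampled
  independently by default; a Gaussian-copula correlation matrix can be
  supplied, but the published tables give no joint structure to calibrate
  one, so independence is the default.
* **Truth partition**: the published 8-subgroup tree — albumin 40.6 g/L at
  the root; age 68, BUN 24.1, NT-proBNP 9,570 pg/mL and albumin 34.5 on the
  low-albumin side; hemoglobin 12.7 g/dL and age 66 on the high-albumin
  side. The NT-proBNP cutoff is printed inconsistently at one place in the
  source (9,750 with ≥); the tabulated 9,570 with strict > is used.
* **Leaf hazards**: the reference (best-survival) subgroup is exponential
  with rate −ln(0.85)/6 ≈ 0.0271/yr (85% survival at 6 years); every other
  leaf multiplies that rate by its published hazard ratio
  (2.72 … 20.38). This proportional-hazards ladder makes Cox HR recovery
  well-posed. Optionally the worst subgroup instead uses a two-piece
  exponential through its printed anchors (48% at 1 year, 11% at 6 years:
  rates 0.734 and 0.295/yr), which matches its early-death profile more
  closely at the cost of exact proportionality.
* **Censoring**: uniform staggered entry over 10 years, administrative cut
  at study end (10 years), and 0.02/yr exponential dropout. On the default
  cohort this yields roughly 45% deaths, similar to the published
  derivation cohort (371/923 ≈ 40%).
* **HF subtype** is assigned with the published composition held fixed
  (largest-remainder counts, shuffled), so the default 1,317-patient cohort
  contains exactly 331/330/656 patients per subtype and the stratified
  split reproduces 923/394. Subtype is independent of the covariates and
  of survival — a simplification; in reality LV dysfunction and subtype are
  nearly the same variable.

Event times are drawn by inverting the piecewise cumulative hazard;
everything is deterministic given (spec, seed).

**What the generator does not emulate.** Covariate correlations (renal
markers, haemoglobin and age are correlated in practice), any smooth
dependence of hazard on covariates (the truth is exactly piecewise-constant
across leaves, which is the favourable case for a tree), informative
censoring, treatment effects, and competing risks. Passing recovery studies
therefore demonstrate the correctness and calibration of the machinery
under the stated data-generating process — not that the published tree
would be recovered from real clinical data.

## Recovery studies and their problem sizes

`survstrat.studies` packages the headline simulation studies; the
acceptance script (`scripts/acceptance.py`) runs them end to end.

* KM calibration: n = 10,000 single-leaf cohorts; the reference leaf is
  checked under administrative censoring at 10 years, the worst leaf
  uncensored so both landmarks are identifiable. Because the reference
  hazard is calibrated through its 6-year anchor only, its implied 1-year
  survival is 97.33% against a printed 97% — a documented 0.33-point model
  offset.
* Tree recovery: replicate cohorts of n = 5,000 from the full default
  spec, fitted with α = 0.05 / Bonferroni / minbucket = 150 on all
  generator covariates. A single cohort recovers exactly 8 leaves only
  ~55% of the time: fitted thresholds sit within ~±0.15 of the truth, and
  patients misrouted inside that margin leave genuine residual signal that
  occasionally supports a ninth split, while a marginal true split
  occasionally fails. The study therefore reports the median leaf count
  and median root threshold over 51 replicates, a stable summary of the
  central recovery behaviour.
* Minimum leaf size: one n = 923 cohort under the default configuration
  (minbucket = 95); the stopping rule makes the bound structural.
* HR-ladder recovery: n = 20,000 cohorts with uniformly assigned true leaf
  labels (so the small best-survival subgroup contributes enough events),
  censoring set to staggered entry over 5 years + administrative cut at
  10 + 2%/yr dropout (≈40% censored); the worst-versus-reference Cox HR is
  the median over 11 replicates.
* Selection power: n = 900, one covariate at log-HR 0.7/SD among 9 nulls,
  baseline hazard 0.2/yr with uniform 10-year censoring (≈40% censored),
  B = 500 bootstrap repeats.

## Known limitations

* The stepwise rule, tie-handling and CI construction of the original
  analysis are unstated; the conventional choices here (Wald-p stepwise,
  Efron ties, Wald CIs) are conventions, not reconstructions.
* Bootstrap stepwise selection inherits the anticonservativeness of
  testing on resampled data; inclusion frequencies are interpretable only
  relative to the 85% threshold, not as selection probabilities.
* The tree offers no surrogate splits and requires complete cases.
* Categorical covariates are limited to 5 levels (exhaustive partitions).
* `AnalysisConfig.ties`, seeds and all thresholds are recorded in the
  report for reproducibility; changing only the seed changes cohort
  membership and bootstrap draws but not the report schema.
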