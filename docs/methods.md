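# Methods

## The estimation problem

Demand for family planning satisfied (DFPS) divides the number of partnered
women 15–49 using contraception (any method, or modern methods only) by the
number *in need* of contraception.  Need requires knowing, for each woman,
her method use, pregnancy/amenorrhea status, fertility intentions and
fecundity — questions many national surveys do not ask.  Contraceptive
prevalence (CPR) uses the same numerator over *all* partnered women 15–49
and is almost universally available.  Because the two indicators share a
numerator and need is a fairly stable fraction of the population, DFPS is
strongly predictable from CPR; this package implements that prediction and
all machinery around it.

## Indicator construction

The analysis population is partnered (married or in-union) women aged 15–49.
Modern methods follow the Hubacher–Trussell technology-based list (condoms,
sterilization, IUD, implants, pills, injectables, emergency pills, patches,
diaphragms, spermicides, rings, sponges); everything else a woman can report
as a current method is traditional.  A woman is **in need** if she (a) uses
any method, or (b) is fecund, not pregnant/postpartum-amenorrheic, and wants
no child within two years (or ever), or (c) is pregnant or postpartum
amenorrheic with a mistimed or unwanted pregnancy.  **Infecund** means any
of: never menstruated; menopausal; no under-five child and last period more
than six months ago; married five or more years with no birth while not
contracepting; self-declares she cannot conceive.

Deliberate design choices at the definition's open corners:

* **Users are always in need** (rule a), regardless of their intention or
  fecundity answers, including sterilized women.  This forces the DFPS
  numerator to be a subset of its denominator, so DFPS ≥ CPR everywhere.
* **Missing answers are condition-not-met**, never grounds for dropping a
  record — consistent with the revised unmet-need definition's goal of
  tolerating incomplete questionnaires.
* **Postpartum amenorrhea window**: 24 months since last birth (the revised
  definitions shortened this window without the value being standard across
  sources); configurable via `NeedConfig.amenorrhea_window_months`.
* **LAM is traditional** by default, since it is absent from the printed
  modern list; the taxonomy is a plain pair of sets and fully configurable.
* **"Undecided" intention is not-in-need** by default, with a switch.
* The five-year exposure window of infecundity rule (iv) is taken as a
  precomputed boolean input field rather than re-derived from birth
  histories.

Estimates are ratios of weighted sums, with strata defined per dimension
(national, subnational region, residence, wealth quintile, education) nested
within country.  Point estimates are the contract; a Taylor-linearised
standard error clustered on the sampling cluster is available as an option.
A stratum with zero denominator weight is returned flagged missing, never as
0/0.

## The predictors and their scale conventions

Both published predictors have the same form on the logit scale,

    logit(DFPS) = β₀ + β_log · ln(CPR) + β_sq · CPR² + β_cd · cpdiff ,

with CPR the prevalence matching the outcome (CPRany for DFPSany, CPRm for
DFPSm) and cpdiff = CPRany − CPRm, a proxy for reliance on traditional
methods.  Defaults: (1.05, 0.93, 2.49, 0.70) for DFPSany and
(1.12, 0.97, 2.13, −1.43) for DFPSm.  Conventions that the source tables
leave ambiguous, resolved here and verified by a consistency check:

* **Everything enters on the proportion (0–1) scale, including cpdiff**,
  even though summary tables print percentages.  Only this convention makes
  the equations reproduce the observed median CPR → median DFPS
  correspondence (0.437 → 0.686 predicted vs 0.680 observed for any;
  0.377/0.343 → 0.571 vs 0.553 for modern).  The tests assert this within
  2 percentage points.
* **log is the natural logarithm** (fractional-polynomial convention).
* **Support bounds**: prevalence below 1% is outside the fitted support and
  is excluded/flagged, never extrapolated; above 0.99 the input is clamped
  (with a flag) to keep the logit finite.
* When only CPRm is available for DFPSm, cpdiff defaults to 0 with an
  explicit per-row note — a documented approximation, not silent behaviour.

The inverse-logit back-transform guarantees predictions strictly inside
(0, 1).  Over the supported CPR range both default predictors are strictly
increasing in CPR at fixed cpdiff, and the cpdiff effect has the sign of
β_cd everywhere (positive for DFPSany — traditional methods still satisfy
need for *any* method; negative for DFPSm).

## Model fitting and selection

Fits are ordinary least squares of logit(DFPS) on an intercept, the
fractional-polynomial transform of the primary CPR, and the extra
covariates.  Design choices:

* **Power set** fixed to the Royston–Altman standard
  {−2, −1, −0.5, 0, 0.5, 1, 2, 3}, degree ≤ 2; power 0 is ln x and a
  repeated power (p, p) contributes x^p and x^p·ln x.
* **Selection statistic**: residual sum of squares (identical ranking to
  Gaussian deviance), ties broken toward fewer parameters, then lower-degree
  powers.  `fp_search` fits every powers multiset of size 1–2 crossed with
  every subset of the candidate extra covariates and returns all fits
  ranked.
* **Cluster-robust variance**: the sandwich estimator clustered on country
  with the Stata-style factor G/(G−1)·(N−1)/(N−k) (statsmodels
  `cov_type="cluster"`), because subnational regions within a country share
  survey machinery and context.  With singleton clusters this reduces to
  HC1 — a property the tests verify numerically.
* **Fits are unweighted** (each region is one analysis unit) and predictors
  are not centred or rescaled before transformation.
* **Exclusion rule**: rows whose relevant prevalence is below 1% are removed
  before fitting, each removal logged.  A 15% threshold reproduces the
  high-prevalence sensitivity restriction, under which
  `compare_linear_fp` tests whether the fractional-polynomial terms beat a
  straight line; the comparison charges 2 degrees of freedom per selected
  power (the Royston–Altman convention), so that searching the power set
  does not masquerade as curvature evidence.

## Cross-validation

`kfold_split` partitions rows by a seeded random permutation into k folds
whose sizes differ by at most one.  `cross_validate` refits the
specification on k−1 folds, predicts the held-out fold, back-transforms to
the proportion scale, and pools all held-out pairs before computing metrics:
bias = mean(predicted − observed), MAE, Pearson correlation, and R² defined
as the squared pooled correlation (the source does not define its
cross-validated R²; this definition is recorded as an interpretation).  MAE
≥ |bias| holds on every dataset by the triangle inequality.  Folds are
simple random partitions of rows, not stratified by country.
`out_of_sample_eval` applies a frozen model to another table — the
cross-dimension design — with no folds and no randomness.

## Synthetic data generator

The generator defines the testing conditions; it emulates the observed
study structure rather than any particular survey:

* **Scale**: 103 countries × Uniform{8..14} regions ≈ 1,100 rows, matching
  the 1,099-region/103-country analysis the predictors come from.
* **CPRany** ~ scaled Beta(1.45, 1.54) on [0.015, 0.848]; **cpdiff** =
  min(CPRany, 0.639) × Beta(0.72, 3.84).  The Beta parameters were
  moment/percentile-matched to the observed multi-country marginals (mean
  41.8%, 10th/50th/90th percentiles 11.8/43.7/69.3% for CPRany; mean 6.7
  p.p., max 63.9 p.p. for cpdiff).  Drawing cpdiff conditionally with
  truncation at CPRany guarantees CPRm ≥ 0; the dependence structure itself
  is an invention, documented as such.
* **Outcomes**: logit(DFPS) = truth equation + country intercept
  perturbation (sd 0.05, drawn per country per outcome — the mechanism that
  makes country-clustered standard errors meaningful) + row noise (sd 0.05,
  chosen so the synthetic cross-validated r² lands in the ≥0.97 regime the
  predictors achieve on real data).
* **Microdata**: a target quadruple (CPRany, CPRm, DFPSany, DFPSm) is
  feasible only if CPRany/DFPSany = CPRm/DFPSm (both equal the in-need
  share); infeasible targets raise an error naming the violated relation.
  Women are drawn multinomially into six categories — modern user,
  traditional user, non-user in need, and three not-in-need types (wanted
  pregnancy/amenorrhea, infecund, wants a child soon, split 25/35/40) —
  and each category's answers are constructed to classify exactly there.
  Weights are Gamma(10, 0.1) (mean 1, design effect ≈ 1.1), independent of
  category, so weighted estimates remain consistent for the targets.

What the generator does **not** emulate: multi-stage sampling geometry
(strata/PSU frames beyond cluster labels), non-response, measurement error
in the survey answers, country-specific questionnaire dialects, or any
systematic lack of fit between the true CPR–DFPS relationship and the
published functional form.  Passing tests therefore demonstrate that the
pipeline is self-consistent and recovers known truth under the model's own
assumptions — not that the published equations are unbiased for any real
country.

## Numerical choices and edge cases

* logit raises on p ∈ {0, 1}; inv_logit uses the numerically stable split
  form.  The generator floors CPRm at 10⁻⁶ purely so the modern-truth
  equation is evaluable on rows that the 1% exclusion rule then removes.
* Rank-deficient designs raise a singularity error naming the collinear
  columns (QR with pivoting); a cross-validation fold that becomes singular
  reports the fold index.
* Proportion columns read from text are auto-rescaled from percent when
  values exceed 1, with a logged notice, because published tables mix
  percent and proportion scales.
* CLI exit codes: 0 success, 2 input/validation failure, 3 numerical
  failure.  Every CLI run writes a `<out>.log.json` sidecar with seed,
  configuration hash and package version.

## Problem sizes used in the test suite

The acceptance-style experiments run at the study's own scale (~1,100 rows,
103 countries): 50 seeds for parameter recovery and specification search,
100 random problems for the OLS oracle, 20 target sets × 10,000 women for
the microdata round-trip.  The full suite completes in well under a minute.

## Known limitations

* Real DHS/MICS recode parsing is out of scope; inputs are clean delimited
  tables with a documented column dictionary.
* All-women (unmarried-inclusive) indicators are not implemented.
* Prediction intervals are not provided (the published fits report
  coefficient confidence intervals, not prediction-interval formulas).
* The reported cross-validated bias of the original analysis (~0.1) sits on
  an ambiguous scale relative to its near-zero out-of-sample bias; this
  package computes all metrics on the proportion scale and makes no attempt
  to reconcile that discrepancy.
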