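# Methods notes

This note records the modelling assumptions, defaults and numerical choices
behind `healthineq`, and what the synthetic-cohort tests do and do not
establish about real survey data.

## The analysis model

### Cardinalizing self-rated health

Self-rated health (SRH) is a 5-level ordinal response. We assume a latent
continuous health index with standard-normal noise, observed through four
ordered thresholds — the ordered-probit model. The fitted linear index
(income term plus controls; thresholds excluded) is taken as each
respondent's cardinal health and min–max rescaled to [0, 1] using the
in-sample extrema. Consequences of these choices:

- The rescaled score **SaH** is invariant to positive affine
  transformations of the latent scale, so the arbitrary location/scale of
  the probit index is harmless.
- SaH is a *predicted* index: it strips the unit-variance individual noise,
  so its correlation with any "true" latent health is bounded by
  sd(signal)/√(sd(signal)² + 1). With this package's default generator that
  bound is ≈ 0.39 — low correlations here reflect a genuinely noisy
  outcome, not a broken fit.
- Income enters as log(1 + income). Post-treatment stage incomes can be
  negative, where the transform extends smoothly as
  sign(x)·log(1 + |x|) (a signed log). For non-negative incomes the two
  coincide.
- The concentration index of SaH is **not** invariant to where the [0, 1]
  anchoring comes from; we always anchor at the in-sample min/max of the
  predicted index, and the Erreygers index is computed with fixed bounds
  (0, 1) on SaH (recorded in output metadata).

Two stage-handling modes exist, because "the income status of the
participant at different stages" can be read two ways:

- `per_stage` (default): the ordered probit is refitted with each stage's
  income as the income regressor, and SaH is re-predicted per stage.
- `fixed`: one fit on initial income; SaH held constant across stages so
  only the income *ranking* changes.

Reports record the mode used; the two give different stage CIs by design.

Optimizer: Newton's method (statsmodels `OrderedModel`), gradient tolerance
1e-8, max 200 iterations, with a BFGS fallback if a Newton step hits a
singular Hessian. Fits are deterministic. A non-converged fit is returned
flagged, and prediction from it is refused, rather than silently degrading.

### Concentration and Erreygers indices

Fractional ranks are (i − 0.5)/n with tied values sharing the average of
their positional ranks; this keeps the mean rank exactly 0.5 and the
covariance and summation forms of the CI identical when ranks are untied.
The CI uses the population (1/n) covariance, matching the summation form.
The Erreygers index follows the bounded-variable formula
(1/n)Σ 4hᵢ/(h_max − h_min)·(2Rᵢ − 1); on [0, 1] health with untied ranks it
equals 4·μ·CI exactly, which the suite verifies to 1e-12.

Stage deltas are consecutive CI differences and telescope:
Δ_total = CI_initial − CI_reimbursement = Σ stage deltas. Positive deltas
mean inequality narrowed at that step.

Income quintiles are cut at the 20/40/60/80th percentiles of **initial**
income and held fixed across stages, so a stage table tracks the same
subpopulation through the scheme; within-group indices recompute fractional
ranks inside the group. Boundary ties go to the lower group. Negative stage
incomes are ranked as-is, never truncated.

### Inference

The data source for this kind of analysis typically ships without a
prescribed variance estimator, so stage and subgroup indices get a seeded
nonparametric bootstrap over individuals (default B = 200): percentile SE
and a two-sided sign-based p-value against 0, starred at p < 0.01.
Degenerate resamples (constant health) are redrawn and counted. Within
bootstrap resamples the cardinalization is held fixed — the SE reflects
sampling noise of the rank–health covariance given the fitted health score,
which is the usual practice and keeps table-sized bootstraps cheap. The one
place where estimation noise of the probit itself dominates — testing a
*null* cohort against CI = 0 — refits the cardinalization inside every
resample (see the recovery suite).

### Relative deprivation

RD is computed on raw SRH treated as integer scores 1–5 (a config flag
allows SaH instead): deprivation is about the ordinal health distribution
itself, and raw scores keep the Gini identity interpretable. The O(n log n)
sorted/suffix-sum evaluation of the decomposed formula
RD(xᵢ) = (1/μ)·r⁺ᵢ·(μ⁺ᵢ − xᵢ) is verified against the O(n²) pairwise
definition and against the Gini of health (Yitzhaki identity) to machine
precision. RD is computed over the full sample by default (not within
quintile); the regression of RD on quintile dummies (lowest quintile as
reference, optionally with gender, age, education years, marital status and
region controls) uses OLS with conventional standard errors.

### Indirect standardization

The utilization models are linear least squares even though the outcomes
are counts — the standardization identities (grand-mean preservation,
need-only reduction) are exact for OLS with an intercept, and the synthetic
generator deliberately produces overdispersed counts so the tests exercise
exactly this mismatch. Need factors: gender, age, SRH (coded 1–5). Non-need
factors: log(1 + income), education years, marital status, urban/rural,
region dummies. Coverage ratios are displayed as percentages rounded
half-up to two decimals; stored values keep full precision.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at a
default size of n = 20,000 (a desk-scale stand-in for a survey an order of
magnitude larger):

- **Income**: lognormal (log-mean 9.8, log-sd 0.8, ≈ 18k currency units
  median per-capita household income per year) — the right-skew typical of
  household surveys.
- **Latent health**: slope·log(1 + income) + covariate effects + N(0, 1)
  noise, thresholded into SRH. Default slope 0.3; default covariate effects
  (female −0.15, age −0.02/yr centered at 50, education +0.02/yr centered
  at 9, married +0.05, urban +0.05) give a modest, survey-realistic
  observable signal. The N(0, 1) noise matches the ordered-probit
  assumption, so cardinalization is well-specified on synthetic data by
  construction.
- **SRH cutpoints**: by default calibrated to latent-sample quantiles so
  the marginal SRH distribution is ≈ 5/18/40/26/11% (very bad → very
  good) — realistic class imbalance for the probit; explicit cutpoints can
  be supplied instead.
- **Premium**: flat 250/year (the scheme is fixed-contribution), fully
  waived for the poorest 5% (premium-assistance policies cover part or all
  of vulnerable participants' contribution; we default to full waiver as
  the simplest case).
- **Utilization**: gamma–Poisson (negative-binomial-like, dispersion 1.5)
  counts, log-linear in standardized need (= −latent health) and
  standardized log-income; bases calibrated to ≈ 4.5 outpatient visits and
  ≈ 0.7 inpatient episodes per year. The income loading is the "non-need"
  channel that the standardization tests switch off.
- **Spending**: unit costs 150/visit and 4000/episode, scaled by an
  income-elasticity multiplier exp(0.2·z) and mean-one gamma noise;
  reimbursement is a fixed 50% of out-of-pocket spending, so
  reimbursement ≤ spending always holds.
- **Demographics**: age ~ N(50, 16) clipped to 18–90; education years from
  {0, 6, 9, 12, 16}; region east/central/west (0.4/0.3/0.3); 50% female,
  80% married, 50% urban — all independent of income, which is what makes
  the null-covariate and exchangeability tests exact.
- An optional extra female log-income slope supports gender-heterogeneity
  experiments; it defaults to 0.

Everything is drawn from one seeded generator: identical config ⇒
byte-identical cohort files.

**What the generator does not emulate**: household clustering, survey
weights, panel structure, item non-response, reporting heterogeneity in
SRH, regional price differences, or any income–covariate dependence. The
joint distribution of income and spending is stylized, not calibrated to
any survey. Passing recovery tests therefore show the *estimators* are
correct and directionally sensitive under clean conditions; they do not
show that real-survey magnitudes would be reproduced.

## Problem sizes and test design

The recovery suites use the sizes at which their claims are stable under
the default effect sizes: slope recovery at n = 20,000; 100-seed
directional claims (downstream CI > 0, RD coefficient ordering,
standardized-utilization gradient) at n = 5,000; the null-cohort CI test at
n = 5,000 with a 60-replicate refit bootstrap. "Increasing standardized
means" is operationalized as a positive least-squares gradient over the
five quintile means — strict quintile-by-quintile monotonicity holds in
most but not all seeds at n = 5,000 and is asserted only on the n = 20,000
default cohort.

## Known limitations

- The latent prediction uses observed covariate values; holding controls
  at their means would change SaH levels (not orderings given the linear
  index).
- CI on min–max-rescaled health is sensitive to the sample extrema
  (a single extreme latent prediction stretches everyone's score); the
  Erreygers robustness companion mitigates but does not remove this.
- Bootstrap p-values are sign-based percentile p-values, granular at 2/B.
- Linear utilization models can predict negative expected counts for
  extreme covariates; coverage ratios are reported as undefined when a
  group's expected mean is non-positive.
- No survey weighting, CI decomposition by determinants, Wagstaff
  normalization, or dominance testing; count models (Poisson/NB hurdle)
  for utilization are deliberately out of scope.
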