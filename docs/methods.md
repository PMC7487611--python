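# Methods

## The model

`pathsem` implements a cross-sectional structural equation model for a
binary cardiovascular outcome with mixed binary/continuous risk-factor
indicators.  Six correlated latent constructs — lipids, anthropometric,
risky behaviour, comorbidities, quality of life, healthy lifestyle —
are measured by 18 observed indicators; three observed covariates (age in
years, sex, family history of CVD) and the six constructs drive the
outcome through a probit link:

* measurement, continuous indicator *j* of factor *k*:
  `y_ij = mu_j + lam_j * xi_ik + eps_ij`, `eps_ij ~ N(0, psi_j)`;
* measurement, binary indicator *j*:
  `y_ij = 1{ mu_j + lam_j * xi_ik + eps_ij > 0 }`, `eps_ij ~ N(0, 1)`;
* structural: `y_i = 1{ alpha + beta' c_i + gamma' xi_i + delta_i > 0 }`,
  `delta_i ~ N(0, 1)`, `xi_i ~ N_6(0, Phi)`.

Identification follows the standard reference-indicator convention: one
loading per factor is fixed at 1 (HDL-C, hip circumference, smoking,
diabetes, environmental QoL, physical activity), every binary residual
variance is fixed at 1 (probit scale), and the outcome residual variance
is likewise fixed, so `delta`'s variance is never sampled.  The six
factors are exogenous and merely correlated; `Phi`'s off-diagonal block
is the model's account of *indirect* relationships among the constructs,
and it is reported as covariances (correlation rescaling is available as
an option, but the published-style intervals of the largest entries
exceed 1, which only a covariance can do).

The link for the outcome is probit rather than logit: with a latent
Gaussian threshold, every full conditional in the sampler is conjugate.

## Estimation

Fitting is by pure Gibbs sampling with truncated-normal augmentation of
all binary variables (indicators and outcome).  Each iteration cycles in
fixed order: augmentation, factor scores, measurement intercepts and free
loadings, continuous residual variances, latent covariance, structural
block.  The update order is part of the reproducibility contract:
identical `(spec, data, config)` give bit-identical draws.

Conditionals:

* factor scores: shared precision `inv(Phi) + Lam' inv(Psi) Lam +
  gamma gamma'`, one Cholesky per iteration, vectorised over subjects;
* measurement: per-indicator bivariate (intercept, loading) normal
  regression of the (augmented) indicator on `(1, xi_k)`;
* residual variances: inverse-gamma `(a0 + n/2, b0 + rss/2)`;
* latent covariance: inverse-Wishart `(nu0 + n, S0 + Xi'Xi)`;
* structural block: one joint 10-dimensional normal draw of
  `(alpha, beta, gamma)` regressing the augmented outcome propensity on
  `(1, covariates, xi)` with unit residual variance.

Truncated-normal draws use upper-tail inverse-CDF inversion
(`x = -ndtri((1-u) * P(Z > a))`), which is accurate to the support
boundary for truncation points out to about ±37; beyond that (where the
tail mass underflows) an exponential tail approximation
`x = a - log(1-u)/a` takes over.  In practice predictors never approach
that region.

Priors (weakly informative, conjugate, standard for Bayesian SEM):
N(0, 10²) on intercepts, free loadings and structural coefficients;
inverse-gamma(2, 1) on residual variances; inverse-Wishart(k + 2, I) on
`Phi` (df 8 for the 6-factor model).  Defaults: 2 chains × 6,000
iterations, 1,000 burn-in, no thinning.  Chain *c* uses seed
`seed + c·10⁶` through `numpy.random.default_rng`; chains start from
data-derived values with chain-specific jitter so the Gelman–Rubin
statistic is meaningful.

Continuous indicators are z-scored inside `fit()` by default, with the
(mean, SD) pairs recorded for exact back-transformation.  For cohorts
produced by the package's own simulator the flag must be off
(`standardize=False`): the simulator already emits indicators on the
standardized scale, and re-scoring would silently rescale the latent
scale fixed by each reference indicator (multiplying recovered structural
coefficients by the reference indicator's SD, ≈1.18 under the default
truth).  `analysis/` drivers and the acceptance script do exactly this.

## Synthetic cohort generator

The source cohort data are request-only, so the generator is the study
bench.  Its defaults encode the study conditions:

* n = 3161 subjects, complete cases, 22 columns;
* age ~ N(48.4, 10²) truncated at 35 (inclusion threshold), sex
  prevalence 0.51, family history 0.06;
* generating loadings, structural coefficients and latent covariances set
  to the published posterior means for the chosen outcome (total CVD,
  stroke, ACS, fatal CVD);
* binary indicator thresholds chosen to reproduce the cohort's marginal
  prevalences (smoking 495/3161, diabetes 324/3161, hypertension
  839/3161) through the probit marginal formula;
* continuous indicators standardized: `mu = 0`, `psi = 1 - lam² Phi_kk`
  where that is positive, else `psi = 0.1` (reference indicators then
  have total variance 1.4, near-deterministic ones such as healthy diet
  slightly above 1);
* outcome intercept calibrated by bracketed root-finding on the
  Monte-Carlo mean of `ndtr(alpha + beta'c + gamma'xi)` (200,000 draws)
  to the observed event rate, 407/3161 ≈ 0.1288 for total CVD.

The published tables print no latent variances, and a unit diagonal is
arithmetically impossible: the printed off-diagonal block with ones on
the diagonal has a negative eigenvalue (−0.012).  Factor variances are
therefore set to 1.3, the smallest 0.1-step value for which the raw
assembly is comfortably positive definite (smallest eigenvalue ≈ 0.29
for total CVD; all four outcome variants are positive definite without
projection, so every printed covariance is kept exactly).  A
nearest-positive-definite projection (eigenvalue clipping at 1e-6) exists
as a guard for user-supplied blocks and logs its projection distance.

What the generator deliberately does not emulate: follow-up time and
censoring (the model is cross-sectional), covariate–factor dependence
(the structural model conditions on covariates without modelling their
joint distribution), raw questionnaire/FFQ items (scores are generated
directly), and raw measurement scales (indicators are standardized; a
de-standardization layer exists only for cosmetic realism).  Passing
recovery tests therefore show that the sampler recovers the truth of
*this* generative family at the study's size and effect structure — not
that the substantive estimates would replicate on real cohort data.

## Diagnostics

* Gelman–Rubin PSRF, classic non-split form
  `sqrt(((n-1)/n W + B/n) / W)` per free parameter (split-chain variant
  available, off by default); headline is the maximum, flag threshold 1.1.
* Monte Carlo standard error by batch means (20 batches, trailing
  remainder discarded).
* Effective sample size via `arviz.ess` (reported, not oracle-checked).
* Posterior predictive p-value: for a thinned subsample of retained
  draws (default 100 per chain) with stored factor scores, replicate data
  are simulated at the draw's parameters and factor scores, and the
  discrepancy — standardized squared residuals for continuous indicators
  plus squared Pearson residuals on the probit mean for binary variables
  and the outcome — is compared between replicate and observed data;
  ties count 0.5.  The discrepancy is pluggable; this default is the
  conventional choice for Bayesian SEM, as the source analysis does not
  state one.  Predicted binary probabilities inside the discrepancy are
  capped at [1e-3, 1-1e-3]: cells with smaller predicted probability are
  effectively unobservable at cohort sizes in the thousands, yet a single
  replicate success in such a cell would contribute an O(1/p) Pearson
  term that dominates the whole statistic.  The cap applies to observed
  and replicate data symmetrically, so calibration is unaffected.

Because `posterior_predictive_p` takes the data to evaluate as an
argument, it doubles as a conformance check: evaluating a *different*
data set against a fitted posterior asks whether that data could have
come from the fitted model.  This is the meaningful form of a
variance-corruption check — the model family is closed under rescaling
any indicator (a free loading, residual variance and latent covariance
absorb it exactly), so corrupting a cohort and refitting correctly
restores calibration; only data the model was not fitted to can be
detected as discrepant.

## Problem sizes in the test and acceptance harnesses

Full study-scale runs (n = 3161, 2 × 6000 iterations, ≈45 s on one CPU)
are used for the headline recovery check and the acceptance script.  The
repeated-replication checks use smaller cohorts so the whole suite stays
quick: PPP calibration uses 20 replications at n = 400 with 2 × 900
iterations (PPP calibration is a distributional property and does not
depend on n); credible-interval coverage uses 20 seeds at n = 800 with
2 × 1500 iterations (nominal coverage likewise holds at any n).  These
sizes are the package's chosen trade-off between Monte-Carlo tightness
and turnaround.

## Known limitations and open choices

* Smoking is coded binary (current smoker vs not); the source cohort's
  three-level status is collapsed, because a fixed-loading reference
  indicator under probit augmentation requires a dichotomy.
* The scale of the risky-behaviour and comorbidities factors is set by a
  *binary* reference indicator, so those factor variances (and the free
  loadings on them) are weakly identified at n = 3161: their sampling
  errors are several times larger than for factors anchored by a
  continuous indicator.  This is a property of the design, not the
  sampler; credible intervals widen accordingly and coverage is
  maintained.
* The lipids and anthropometric factors are nearly collinear under the
  generating truth (implied correlation ≈ 0.76), so their two structural
  coefficients are individually the hardest parameters to pin down
  (known-factor-scores Fisher SE ≈ 0.055 each at n = 3161); their sum is
  much better determined.
* No ordinal indicators, no missing-data imputation, no structural paths
  between latent factors, no time-to-event component, and no
  product-of-paths mediation estimator (the exogenous-correlated-factor
  model tabulates only the covariance block).
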