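# Methods

This package re-implements, as a tested pipeline over synthetic data, the
statistical core of a validation study comparing anthropometric adiposity
indices (BMI, waist circumference WC, hip circumference HC) against
whole-body MRI measures of body composition (total body volume TBV, total /
subcutaneous / visceral / coronary adipose tissue TAT / SAT / VAT / CAT, and
skeletal muscle tissue SMT) in ~600 men and ~600 women aged roughly 49–81.
The pipeline stages are: cohort generation → residual-method age/height
adjustment → correlation matrices with Fisher-z CIs → multiple regression
with type-II partial correlations, VIFs and bootstrap optimism → the
measurement-error implication for relative-risk estimates.

## Residual-method adjustment (`bodycomp.adjust`)

Each variable (predictors *and* outcomes, BMI included) is regressed by OLS
on an intercept, sub-study age and height within sex, and replaced by its
residuals. Residuals are left at mean zero: every downstream statistic used
here (Pearson r, R², partial r) is location-invariant. Covariates enter
linearly; no spline or nonlinear option is provided. Age defaults to
sub-study age (the age at which the MRI and anthropometry were taken); the
covariate list is a plain argument, so weight-change-style analyses with a
different covariate set are the same operation on a complete-case subset.

## Correlation machinery (`bodycomp.corrstats`)

* **Fisher-z CIs**: z = atanh(r), SE = 1/√(n−3), normal quantile. This
  reproduces the reference interval (0.77–0.83) for r = 0.80 at n = 598. For
  r = 0.96 at n = 598 the method gives a lower bound of 0.95 where the
  source table prints 0.96 — an artifact of rounding r before publication,
  recorded, not forced.
* **Matrix-level R²**: for standardized variables, R² = cᵀR⁻¹c where c holds
  outcome–predictor correlations and R the predictor intercorrelations;
  solved with a linear solve, never an explicit inverse.
* **Partial correlations from a correlation matrix**: magnitude from the
  R²-increment identity r_p² = (R²_full − R²_reduced)/(1 − R²_reduced), sign
  from the standardized full-model coefficient. An independent
  precision-matrix route (−P_ij/√(P_ii P_jj)) is computed alongside and must
  agree to 1e−8; the two routes agreeing is also a property test and an
  acceptance check against the sample-level type-II implementation.
* **PSD repair** (`nearest_psd`): printed 2-decimal matrices can be
  indefinite; eigenvalues are clipped at 1e−8 and the diagonal re-normalized,
  iterating until the minimum eigenvalue is non-negative, so the operation is
  exactly idempotent. (The two transcribed matrices here happen to be
  positive definite already.)
* Comparisons against printed values use round-half-up: 2 decimals for
  correlations, whole percent for R².

## Regression engine (`bodycomp.regmodel`)

OLS on the residual-adjusted variables. "Type II sum of squares" partial
correlations are the SSE comparison between the full model and each
leave-one-predictor-out model, signed by the full-model coefficient. The
partial-r CI uses Fisher z with SE 1/√(n − k − 3), k = number of conditioned
covariates — a declared convention (the source never names its CI method).
VIF_j = 1/(1 − R² of x_j on the other predictors); a VIF beyond 1e6 raises a
collinearity error.

**Bootstrap optimism**: B = 100 resamples (rows with replacement, within the
sex stratum because every model is sex-stratified); per replicate the
refitted model's bootstrap R² minus its R² evaluated on the original sample;
optimism = mean difference; corrected R² = apparent − optimism. A note on
scale: for pure-noise models at small n the true optimism is substantially
larger than the expected apparent R² of p/(n−1), because the out-of-sample
R² of a noise model is negative; the unit tests check the bootstrap against
a brute-force fresh-sample oracle rather than against p/(n−1).

## Synthetic cohort generator (`bodycomp.synth_cohort`)

The generator emulates the validation design: 12 strata (2 sexes × 2 centers
× 3 ten-year baseline age bands), default 100 subjects per stratum. Baseline
age is uniform within band; sub-study age adds a uniform 14–17-year
follow-up lag (the recruitment window spanned ~4 years and the imaging
campaign ~2, so individual lags vary; uniform is a convention, not a
reported fact). Center effects are not modeled (the published marginals were
nearly identical by center).

**Marginals.** Published cells give mean (min, max) only. Spreads use the
range rule sd = (max − min)/4 (configurable to /6): for ~200 near-Gaussian
observations the range spans ≈4 SD. Per-variable mean *lines* in age are
weighted least-squares fits through the three published band means, so
monotone age trends (SMT falling, VAT/CAT rising) are reproduced; the
mid-band peak of BMI/WC/HC is flattened to its linear trend — a deliberate
simplification that keeps the mean structure exactly linear in (age, height)
and therefore exactly removable by the residual method.

**Height and the BMI–height correlation.** Height is its age line plus
truncated-Gaussian noise (±3 SD, which also bounds conditional means for the
positivity argument below). Each other variable adds a height-deviation term
slope_h·(height − height-line(age)); the BMI slope is solved in closed form
so the population within-sex BMI–height correlation is 0.2, the value that
motivates height-adjusting BMI at all. Other slopes are plausibility
defaults in `GeneratorConfig` (e.g. 0.18 L/cm for SMT); they do not affect
the adjusted-scale correlation targets, which the adjustment removes them
from.

**Correlation structure with exact additivity.** TAT = VAT + SAT + CAT and
TBV = TAT + SMT + rest hold exactly because TAT and TBV are computed sums.
The published 9×9 adjusted-correlation targets include those sums, so the
covariance of the 8 *basic* variables (BMI, WC, HC, VAT, SAT, CAT, SMT,
rest) is fitted by least squares such that the induced correlation matrix of
the 9 published variables matches the printed one; the printed matrices came
from real data in which additivity held, so a small-residual solution exists
(max |induced − printed| = 0.003 men / 0.004 women). The "rest" compartment
(bones, organs, fluids, lung air) is uncharacterized in print; its mean
closes the TBV identity band by band, its SD and correlations are free
parameters of the fit, lightly regularized toward plausible values.

**Positive, skewed volumes with exact linear covariances.** Residuals follow
a Gaussian copula with shifted-gamma margins: margin i is
σ_i·(Q_gamma(Φ(z); k_i) − k_i)/√k_i, mean 0, variance σ_i², bounded below at
−m_i with k_i = (m_i/σ_i)². For volume components m_i is 0.9 × the
worst-case conditional mean (minimum of the age line minus the largest
height effect), which makes every generated volume strictly positive by
construction; for anthropometry m_i = 3σ_i (mild right skew, as in real BMI
and circumference data). The Gaussian-scale pair correlation that yields
each target *linear* correlation is solved by 40-node Gauss–Hermite
quadrature and root-finding, so linear covariances — and hence the
covariances of the derived sums — are matched exactly in expectation.
Right-skewed margins are both physiologically realistic (VAT and CAT have
CV ≈ 0.5–1) and the reason recovery tolerances are checked by simulation:
skewness inflates the sampling noise of Pearson correlations relative to
Gaussian data. At 50,000 subjects per sex the maximum absolute deviation of
the adjusted sample correlations from the printed targets is typically
0.005–0.009.

Waist and hip are the mean of three noisy tape readings (SD 0.3 cm per
reading), applied after correlation calibration; the induced attenuation of
correlations is O(10⁻⁴) and ignored. Weight is derived as BMI·(height/100)²,
so the BMI identity holds exactly. Weight change since early adulthood is
current weight minus a simulated early-adult weight (early BMI tracks
current BMI with coefficient 0.35) plus recall noise, with the reference
missingness rate 97/1192 injected at random. An exclusion operation flags
round(rate·n) records as MRI failures (deterministic count, random
identity); the reference rate 42/1234 reproduces the published 1,192 usable
records. Optional clipping to the published min/max ranges is off by
default because truncation distorts correlations.

**What the generator does not emulate:** center differences, the mid-band
non-monotonicity of anthropometric means, within-subject longitudinal
structure, and any image-level properties. Passing recovery tests therefore
show the *pipeline* is correct under the published moment structure, not
that real MRI data would behave identically.

## Attenuation module (`bodycomp.attenuation`)

The study's headline implication: a risk model using anthropometry-predicted
compartment volume instead of the true volume underestimates the log
relative risk by the calibration R². The module simulates the canonical
classical-measurement-error structure under which this is exact: true
exposure T ~ N(0,1); proxy X = T + U with independent U ~ N(0, (1−R²)/R²),
so corr(X,T)² = R²; outcome log-linear (Poisson), rare-outcome logistic, or
linear in T; the naive model fitted on X estimates β·R² because
E[T|X] = R²·X under joint Gaussianity. For the logistic model the
equivalence relies on the rare-disease approximation; a warning fires above
a 10% event rate. `attenuation_from_validation` maps a fitted calibration
model to its predicted bias factor (the model R², and the
optimism-corrected variant when present). Attributable-risk attenuation is
not formalized here.

## Problem sizes and numerical choices

Default analyses run at the study's own scale (≈600 per sex); statistical
calibration checks use 12,000 per sex and the recovery check 50,000 per sex,
sizes at which Monte-Carlo error is comfortably below the stated tolerances
while the full suite runs in a few minutes. Matrix solves use
`numpy.linalg.solve`/`lstsq` (never explicit inverses); the component-
covariance fit is `scipy.optimize.least_squares` with a PSD barrier; all
randomness flows through `numpy.random.default_rng(seed)` and identical
seed + config produce byte-identical cohort files.

## Known limitations

* The printed predictor intercorrelations (BMI–WC 0.91/0.89, BMI–HC
  0.86/0.93, WC–HC 0.82/0.85) imply VIFs of ≈7.5 (men) and ≈10 (women) for
  BMI — at odds with the source's own statement that all VIFs were below 6.
  Cohorts calibrated to the printed matrices therefore cannot satisfy a
  VIF < 6 check; the discrepancy is inherent to the published numbers, not
  to the implementation.
* The women's VAT model R² computed from the rounded printed matrix is 66%
  where the source prints 67% — a rounding artifact, left as computed.
* Recovery of the printed correlations is limited by the self-consistency
  residual of the printed tables (~0.004) plus skew-inflated sampling noise;
  the generator targets the printed matrices, not an idealized exact copy.
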