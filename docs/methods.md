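# Methods

This note records the models `twinsle` implements, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot establish.

## Outcome scale

The symptom score sums nine diagnostic criteria each rated 0 /
subthreshold 0.5 / 1 / strongly present 1.5. Count likelihoods need
integers: when a score column contains half-point values the whole
column is doubled (`io.integerize_scores`), which under a log link
shifts only the intercept by log 2 and leaves every rate ratio
untouched. Integer-valued columns (all simulated cohorts) pass through
unchanged, because doubling a Poisson count would break its
mean–variance relation and distort the observation-level variance
estimate. Half-point scores therefore arise only in real data; the
generator draws integer counts truncated at the number of criteria
(9 by default — the truncation binds for ~0.3% of measures under the
default conditions).

## Synthetic twin cohorts (`simulate`)

Per pair: an additive-genetic value `a` shared fully by MZ co-twins and
with correlation 0.5 between DZ co-twins (common + unique construction,
each twin marginally N(0, σ²_A)); a shared-environment value
`c ~ N(0, σ²_C)` per pair; a stable nonshared value `e ~ N(0, σ²_E)` per
twin; and an observation-level residual `r ~ N(0, σ²_R)` per twin-wave
row. The log rate of the symptom count is

```
η = μ₀ + β_wave·1{wave 2} + β_sex·1{male} + Σⱼ γⱼ·SLEⱼ + a + c + e + r.
```

Exposure j is a liability-threshold draw: indicator that
`w_Aⱼ·a + w_Cⱼ·c + ε` (ε standard normal) exceeds the threshold solved
analytically from the normal CDF at total liability variance
`w_Aⱼ²σ²_A + w_Cⱼ²σ²_C + 1`, so the marginal prevalence equals the
configured value exactly, whatever the loadings. Exposures are drawn
once per twin (they are measured once, retrospectively) and repeated on
both wave rows. The `w` loadings are the package's device for inducing
gene–environment correlation and family-environment selection; the
study the package models reports no generative mechanism for them.

Default conditions (`paper_like_config`): 1400 pairs in the five
zygosity-by-sex groups of the study's first wave (451/222/265/119/343);
exposure prevalences from the study's exposure table over 5075 measures
(three never-endorsed cells floored at 5·10⁻⁴ to stay inside (0,1));
variances A = 0.36, C = 0.24, E = 0.17, residual = 0.59 (the study's
baseline estimates); wave effect log 0.65 and sex effect log 1.05; μ₀ =
−1.05, chosen once so the marginal mean symptom count is ≈ 0.65, the
study's mean predicted count. Causal effects default to half of each
reported elastic-net log-RR, with the remaining association induced as
confounding through `w_C = 0.30` (childhood) / `0.15` (adulthood) and
`w_A = 0.15` on the selected events — a deliberate
partial-causation-plus-family-selection world, matching the study's
qualitative conclusion.

What the generator does **not** emulate: attrition between waves,
recall error in retrospective reports, age at event, sex-limited or
age-moderated genetic effects, and reverse causation of symptoms on
exposure. Passing tests therefore certify the estimators under the
assumed data-generating model, not the epidemiology of real registry
data.

## Count regression (`count_regression`)

Poisson or NB2 negative-binomial log-link GLMs (statsmodels), with a
CR0 pair-clustered sandwich covariance (no small-sample factor; the CR1
degrees-of-freedom correction is available via `cov_type="CR1"`). With
singleton clusters CR0 reduces exactly to HC0, which the tests assert.
Zero-variance covariates (never-endorsed events) are dropped and
reported as omitted with RR 1. Overdispersion is tested by the
likelihood ratio of NB2 against Poisson referred to the boundary
mixture ½χ²₀ + ½χ²₁; a negative fitted dispersion (the underdispersion
direction) counts as zero evidence, which keeps the test one-sided and
calibrated (type-I error ≈ 5% in the null simulation).

## Elastic net and the polyevent score (`polyevent`)

The solver is penalized IRLS with cyclic coordinate descent, warm starts
along a descending 100-point log-spaced λ path from the analytic λ_max,
and exact KKT conditions as the convergence check — the glmnet strategy,
written against the objective
`(1/n)Σ(μ − yη) + λ(α‖β_pen‖₁ + (1−α)/2‖β_pen‖₂²)`. Binary indicators
are left unstandardized so each coefficient exponentiates to a per-event
rate ratio; consequently λ values are not transferable to analyses that
standardize. Sex and wave are unpenalized (the study reports them as
fixed effects beside the selected events). Cross-validation uses mean
out-of-fold Poisson deviance on a common λ path, with the fold unit
being the twin (both waves together; pair-level folding available), and
the strict CV minimum — no one-standard-error rule — selects (α, λ).
R's glmnet, fitted on the same design with the same objective, serves as
an independent oracle in the test suite (agreement to 2·10⁻³), and the
λ → ∞ / λ = 0 limits are checked against full shrinkage and the
unpenalized MLE. The risk score is the predicted symptom count
(rescaled back to the criteria scale if the outcome was doubled); its
correlation with the observed score is reported at wave 1, the initial
single-time-point measure.

## Biometric co-twin model (`cotwin_ace`)

Within a pair the fixed-loading random effects collapse into
independent blocks: one pair-level component with variance
`share·σ²_A + σ²_C` (share = 1 for MZ, 0.5 for DZ), two individual
components with variance `σ²_E` (MZ) or `0.5σ²_A + σ²_E` (DZ), and, for
the Poisson family, one component per observation with variance σ²_R (a
lognormal-Poisson overdispersion term — the "residual variance" row of
the output). The implied genetic variance is σ²_A per individual and
the implied within-pair genetic covariance σ²_A (MZ) / 0.5σ²_A (DZ), as
the design tests verify against closed form and Monte Carlo.

**Estimation.** The marginal likelihood factorizes over pairs and is
evaluated by nested adaptive Gauss–Hermite quadrature: the
observation-level integral is a one-dimensional Poisson-lognormal
integral, computed by 30-node Gauss–Hermite on a dense grid per distinct
count and interpolated with cubic splines (clipped at the grid edges so
splines never extrapolate); the twin- and pair-level integrals use
9-node Gauss–Hermite centered and scaled by the joint Laplace mode and
curvature, which a batched Newton iteration supplies. The quadrature
matches brute-force integration to < 10⁻³ log-likelihood units per
pair in validation. A plain Laplace backend (`backend="laplace"`) is
retained as a fast path; on its own it is materially biased here (one
Poisson observation per residual effect is Laplace's worst case),
which is why the quadrature backend is the default. Optimization is
L-BFGS-B over fixed effects and standard deviations (bounded at zero,
so variances are nonnegative by construction; estimates below 10⁻⁴ are
flagged as boundary), started from the Laplace optimum. AIC is
−2·loglik + 2·(free parameters), with thresholds counted for the
probit family.

**Probit variant.** The score is coded into ordered categories at every
observed level; thresholds are estimated as an increasing sequence (free
first threshold, log increments), there is no intercept, and the
residual liability variance is fixed at 1 for scale identification. The
Gaussian identity family is included as an exactly-integrable debug
family and is checked against classical moment estimators
(2(r_MZ − r_DZ)).

**Standardization and comparisons.** A, C, E are standardized by their
own total (residual excluded), rounded percentages summing to 100 ± 1.
`compare_decomposition` reports per-component percent decreases to one
decimal (undefined when the baseline component is at the zero boundary)
and the total percent of stable variance explained to the nearest
integer. `compare_aic` refuses fits of different data or families
(SHA-1 fingerprint of outcome and pair ids).

**Within/between decomposition.** Exposure is split into pair mean and
within-pair deviation (Begg–Parides style rather than pair fixed
effects), deviation slopes estimated separately for MZ and DZ strata,
with an optional extra DZ between-pair term. Poisson effects come from
the cluster-robust GLM; the probit variant uses an ordered probit with a
cluster sandwich assembled from per-observation scores. Strata without
within-pair exposure variance report a missing within effect.

## Identifiability of the A/C split at study scale

A practical finding the tests encode: at the study's information level
(mean count ≈ 0.65, 1400 pairs) the profile likelihood is nearly flat
along the A + C = constant direction, because Poisson measurement noise
on the log scale (≈ 1/μ ≈ 2) dwarfs the 0.18 MZ–DZ covariance contrast
that separates A from C. Single-fit A/C estimates consequently carry
sampling SDs of ~0.15–0.2 even for the exact-likelihood estimator
(verified against brute-force integration), while E, the residual, and
the A + C total are precise. Replicate averages recover all four
components closely (the recovery test asserts mean recovery within 0.08
per component over 20 replicates, and per-replicate precision for E and
the residual). Single-cohort A/C splits — including on real data of
this size — should be read with that flatness in mind.

## Numerical conventions

Tolerances: inner Newton gradient < 10⁻⁸; L-BFGS-B `ftol` 10⁻¹⁰ with
finite-difference step 10⁻⁵ (sized above the quadrature's numerical
noise); coordinate descent converges on weighted parameter changes
< 10⁻⁸ plus exact KKT verification at 10⁻⁶. Variances are floored at
10⁻⁸ inside the quadrature; rates are clipped at exp(±40). Degenerate
inputs fail loudly: non-finite simulated rates name the offending
parameters, constant outcomes make the probit family refuse, empty
cohorts tabulate to empty tables, and schema violations are enumerated
in full on read.
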