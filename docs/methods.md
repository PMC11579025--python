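# Methods

## The problem

A genetic variant can associate with a quantitative trait in two distinct
ways: by shifting the trait level uniformly across adult life, or by changing
the *rate* at which the trait changes with age. For kidney function measured
as eGFR (estimated glomerular filtration rate, mL/min/1.73 m²), the second
pattern — accelerated decline — is the clinically interesting one, because
faster decline leads to kidney failure. Separating the two requires
longitudinal data and a model in which the allele effect is allowed to depend
on age.

`longgwas` implements a family of estimators for the per-allele, per-year
decline effect, a simulation benchmark that measures their type-I error,
power and bias, an efficient genome-wide interaction scan, and the follow-up
procedures built on top of the fitted models.

## Models

For person *i* with assessments *t = 1…nᵢ* at ages *age_it*, trait values
*y_it*, and allele dosage *G_i ∈ [0, 2]*:

**Age-interaction mixed model** (the primary estimator; "age model RI&RS"):

    y_it = b0 + b1·sex_i + b2·age_it + b3·G_i + b4·age_it·G_i
           + g0_i + g1_i·age_it + e_it

with (g0_i, g1_i) bivariate normal with covariance D (standard deviations
σ₀, σ₁ and correlation ρ), e_it iid N(0, σ_e²), and e independent of the
random effects. `beta_decline = b4` (per allele per year) and
`beta_main = b3`, the allele effect on the trait level at age 50 thanks to
age-centering. Variants: *uncorrelated* forces D diagonal; *RI-only* drops
g1 entirely (and, by ignoring slope heterogeneity, badly understates the
uncertainty of b4 — the benchmark quantifies the resulting inflation).

**Time model RI&RS**: the same structure over time-since-first-assessment,
adjusting for age at baseline. Appropriate when the trajectory start is
informative (e.g. disease onset); its `beta_main` is baseline-conditioned and
flagged non-comparable to the age model's.

**Difference model**: per-person (last − first value)/(age span), ordinary
least squares on dosage. Uses only two points per trajectory.

**BLUPs&LinReg**: two-stage — fit the age model *without* SNP terms, extract
per-person best linear unbiased predictions (BLUPs) of the slope deviation,
regress them on dosage. BLUPs are shrunken toward zero by design
(factor σ₁²/(σ₁² + σ_e²/S_xx) in a balanced design with age dispersion
S_xx), so the second-stage coefficient is biased toward zero by the same
factor; the benchmark measures this as a strong negative relative bias while
the type-I error stays calibrated (the null is preserved under shrinkage).

Singletons — persons with one assessment — carry no within-person change
information but stabilise level terms and variance components; only the
one-stage mixed models can use them.

## Estimation

REML (ML available for nested likelihood comparisons) on the profiled
likelihood. The relative random-effect covariance Θ = D/σ_e² is parameterized
by its log-Cholesky factor, so D is positive semidefinite by construction and
the optimization is unconstrained (L-BFGS-B, relative tolerance 1e-8,
iteration cap 500, Nelder–Mead polish if the first pass reports failure).
β and σ_e² are profiled out in closed form.

All computations are block-wise per person: only the per-person
cross-products Z'Z, Z'X, Z'y (Z the random-effect design, q = 2 columns,
or 3 with a quadratic random term) enter each likelihood evaluation via the
Woodbury identity, so the cost per evaluation is linear in the number of
records and, after the one-time cross-product pass, linear in the number of
persons. A dense multivariate-normal likelihood is kept in the test suite as
the oracle for this algebra.

Internally the age axis is transformed to (age − 50)/10 and time to time/10
for well-conditioned optimization; every reported effect and variance
component is back-transformed to per-year units. Wald tests use the normal
reference, which is standard at GWAS sample sizes.

Boundary fits (variance ≈ 0 or |ρ| ≈ 1) are returned flagged, not rejected,
and enter benchmark summaries; non-convergence is likewise a flag, never an
exception or a silent retry.

## Genome-wide scan

Refitting the mixed model per variant is unnecessary: the SNP-free age model
is fitted once, and each variant is evaluated by a score test. For dosage
column G and interaction column K = G·(age − 50), the joint score is
U = [G,K]' P y with P the residual-forming projection of the null
generalized-least-squares fit; the decline test conditions K on G through the
score covariance and refers the quadratic form to χ²₁. Both columns are, per
person, the dosage times the random-effect design, so all quadratic forms
reduce to cached 2×2 / 2×p person blocks — O(persons) per variant.

The one-pass score holds variance components at the null estimate. For a
variant with a real (or chance) effect, a full refit attributes part of the
slope variance to the variant, making the score's tail statistic slightly
conservative relative to the refit Wald test. The scan therefore refines
variants whose initial score p falls below 0.05 with an exact REML Wald test
of the augmented model, warm-started at the null variance parameters and
assembled entirely from the cached cross-products (still O(records) per
refined variant, and only a few percent of variants under the null). With
refinement the scan p agrees with an independent per-variant refit to within
|Δlog₁₀p| ≈ 0.02 at 500 persons; pass `refine_p=None` for the textbook
one-pass score test.

Residual inflation is summarised by genomic control, λ = median(χ²)/0.4549,
applied to the decline test only; corrected p = upper tail of χ²/λ. Variants
with MAF < 0.5% are skipped. Significant variants (default GC-corrected
p < 5×10⁻⁸) are clumped into loci: lead = smallest p, window ±250 kb,
overlapping windows merged, ties broken by (chromosome, position).

## Synthetic data

The generator draws hard genotypes {0,1,2} under Hardy–Weinberg proportions
at a configurable allele frequency and builds trajectories from the
generative form of the age-interaction model (sex effect available but off
by default). Two presets encode the study designs the benchmark emulates:

* `ukb_like` — biobank-style: ~50% singletons; age at first assessment
  N(57, 8²) truncated to [35, 78]; non-singletons get 2 + Poisson(4) visits
  spread uniformly over a Uniform(4, 12)-year window. Trait parameters:
  level 104 at age 50, mean decline −1.0/yr, σ₀ = 12, σ₁ = 0.8/yr
  (within the 0.66–0.95/yr range estimated for adult eGFR), ρ = −0.2,
  σ_e = 5, EAF 0.3. The effect size used for power/bias runs is
  −0.025/yr per allele.
* `cohort_like` — panel-style: ~20% singletons, scheduled waves every
  5 years with 20% per-wave attrition (whole later visits dropped at
  random), recruitment ages 25–74.

Every field is overridable, so externally estimated parameter sets can be
dropped in verbatim. What the generator does *not* emulate: linkage
disequilibrium between variants, imputation uncertainty, informative
drop-out, assay changes over calendar time, and non-linear population age
trends. Passing benchmarks therefore demonstrate the statistical properties
of the estimators under the stated generating model, not robustness to
those real-data complications.

## Benchmark harness and problem sizes

Per replicate the harness draws fresh genotypes and trajectories, runs every
requested approach, and aggregates rejection rates at α = 0.05 (exact
Clopper–Pearson 95% intervals), relative bias 100·mean((β̂ − β)/β), and
convergence rates. Fixed seed ⇒ bit-identical summaries; failures are
counted, never resampled.

Default desk-scale profile: 1,000 persons per replicate. Calibration and
bias use 600–8,000 replicates (type-I error has MC SE ≈ 0.5% at 2,000
replicates; relative bias has MC SE ≈ 3% at 8,000, since the per-replicate
interaction SE at n = 1,000 is ~3× the benchmark effect size). Statistical
power at −0.025/yr separates the approaches by only a few percentage points
at n = 1,000, so the power-ordering check uses 250 replicates of 20,000
persons, where all approaches see the same data and the ordering is stable.
These sizes are the package's reduced-scale defaults; the harness accepts
any scenario overrides for full-scale reproduction.

## Follow-up procedures

* **Non-linearity.** Quadratic terms can be added to the global age trend,
  the person-specific random part, or the allele interaction; the linear
  decline estimate is reported with and without augmentation. Breakpoint
  models add a hinge (age − knot)₊ to both the global and allele terms at
  knots 40/50/60; the hinge nests the linear model, and with a knot at the
  minimum observed age the hinge column is collinear with the linear one, so
  out-of-range knots are rejected. Random slopes absorb part of any real
  curvature/hinge signal, which attenuates these tests — an inherent
  property, not an implementation artifact.
* **Variability screen.** A Gaussian location-scale model (mean Xβ, log-SD
  Wα, records treated as independent) estimates an allele effect on trait
  spread. This answers a different question than association with trait
  change — a decline effect also widens the cross-sectional spread at older
  ages — and is provided as a screen with that caveat.
* **Effect curves and classification.** Allele effect on the trait level at
  age a is beta_main + (a − 50)·beta_decline. "Stable-effect" variants are
  those with p_main < 5×10⁻⁸, |beta_main| > 0.50, p_decline ≥ 0.1,
  |beta_decline| < 0.005 and SE_decline < 0.005 — strong, age-independent
  level effects.
* **Enrichment.** One-sided exact binomial upper tail P(X ≥ k) with per-
  variant null probability p₀ = 0.05 (a variant is "successful" if its
  association is nominally significant and directionally consistent; under
  the null that event has probability 0.05, not 0.025, because direction is
  determined by the significant effect's sign).
* **Clinical traits.** Rapid-decline cases decline faster than −3/yr
  (global slope + BLUP deviation), controls lie in [−1, +1]/yr, others are
  unlabeled; per-variant logistic regression adjusts for baseline age, sex
  and covariates. The CKD subset keeps persons ever below 60 and drops
  records before the first sub-threshold value; because that first retained
  timepoint is informative, decline testing in the subset uses the time
  model. No correction for index-event bias is attempted.
* **Polygenic score.** Σ weight·dosage with per-allele decline weights and
  allele-orientation checking; tested as the "dosage" in the age model with
  singletons included, with study-membership indicators as covariates.

## Numerical choices and edge cases

* Optimizer start: Θ = I on the internal scale. Monotonicity of accepted
  steps and a dense-likelihood oracle are enforced in tests.
* Degenerate inputs: monomorphic variants are flagged and skipped, not
  tested; zero age spans make the difference model error; a constant
  polygenic score errors rather than returning a degenerate test.
* Effect-allele orientation: results are reported for the stated effect
  allele; flipping alleles negates both effects exactly (tested).
* The exclusion cascade applies its rules in a fixed order (person flags,
  age/date floor, dialysis, transplant/ESKD window, prior-low-value, 10-SD
  outlier screen against the SNP-free age-model fit, winsorize to
  [15, 200]); the outlier screen is applied once, not iterated, and
  date-based rules are skipped (and audited as skipped) when no dates are
  supplied.

## Known limitations

* One grouping level (person); no kinship/relatedness matrices, so close
  relatives should be pruned upstream.
* Gaussian traits only; no binary-trait GLMMs or survival joint models.
* The location-scale screen ignores within-person correlation by design.
* Small-sample score-test corrections (saddlepoint) are not implemented;
  at desk scale the refinement stage covers the relevant tail.
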