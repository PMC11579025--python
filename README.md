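# longgwas

Linear-mixed-model GWAS of longitudinal trait change, with kidney-function
decline (eGFR) as the role model.

## The problem

Cross-sectional GWAS have mapped hundreds of loci for kidney function, but a
variant can lower eGFR in two very different ways: by a constant offset
across adult life ("stable effect") or by accelerating the age-related
decline. Only the second pattern marks progression toward kidney failure.
Distinguishing them needs repeated measurements per person and a model in
which the allele effect depends on age — and, at genome scale, an estimator
that is simultaneously calibrated, powerful, unbiased, and cheap enough to
run on millions of variants.

`longgwas` is a toolkit for exactly that, aimed at statistical geneticists
and epidemiologists working with biobank or cohort trajectory data. It
provides:

* **Seven association approaches** behind one interface: the difference
  model (last − first)/(age span); one-stage mixed models over
  time-since-baseline or age-at-exam with random intercepts and slopes
  (correlated, uncorrelated, or intercept-only); the two-stage
  BLUPs-then-linear-regression shortcut; and the age model including
  "singletons" (persons with one assessment).
* **A REML mixed-model core** with block-wise per-person likelihood
  (cost linear in records) and a log-Cholesky variance parameterization.
* **A simulation benchmark** of type-I error, power and bias with exact
  binomial confidence intervals.
* **A null-fit-once genome-wide interaction scan**: score tests against a
  single SNP-free fit, exact Wald refinement in the tail, genomic-control
  correction, ±250 kb locus clumping.
* **Follow-up procedures**: quadratic and breakpoint (hinge) age effects, a
  location-scale variability screen, age-dependent effect curves,
  stable-effect classification, exact binomial enrichment tests, rapid
  decline and CKD-subset progression traits, decline polygenic scores.
* **Data handling**: long-format phenotype I/O, dosage matrices and VCF
  (`DS` field), the race-free CKD-EPI 2021 creatinine equation, and the
  audited record-exclusion cascade for eHR-derived eGFR trajectories.

## The central model

For person *i* at exam *t* with age *age_it*, trait *y_it* and allele dosage
*G_i*:

    y_it = β₀ + β₁·sex_i + β₂·age_it + β₃·G_i + β₄·age_it·G_i
           + γ₀ᵢ + γ₁ᵢ·age_it + ε_it

with (γ₀ᵢ, γ₁ᵢ) ~ N(0, D) (correlated random intercept and slope) and
ε_it ~ N(0, σ_e²). The decline effect is β₄ (trait units per allele per
year); with age centered at 50, β₃ is the allele effect on the trait level
at age 50, and the allele effect at any age is β₃ + (age − 50)·β₄. See
`docs/methods.md` for the other estimators, the score-test scan, and all
numerical choices.

## Worked example

Simulate a biobank-style dataset (1,000 persons, ~50% with a single
assessment, one variant with EAF 0.3 accelerating decline by 0.025 per
allele per year) and test it with the primary estimator:

```python
import longgwas as lg

cfg = lg.make_scenario("ukb_like", n_persons=1000, beta_decline=-0.025)
data, genotypes = lg.simulate_dataset(cfg, seed=42)

res = lg.run_approach("age_ri_rs_singletons", data,
                      genotypes.dosages[0], genotypes.person_ids)
print(f"beta_decline = {res.beta_decline:+.4f}  (SE {res.se_decline:.4f}, "
      f"p = {res.p_decline:.3g})")
print(f"beta_main    = {res.beta_main:+.3f}  (allele effect at age 50)")
```

Output:

```
beta_decline = -0.0440  (SE 0.0654, p = 0.501)
beta_main    = +0.401  (allele effect at age 50)
```

The point estimate (−0.044/yr) brackets the simulated −0.025/yr but a
single 1,000-person replicate has SE ≈ 0.07 — individual-variant decline
effects of this size only become detectable at biobank scale, which is the
benchmark's point. The same battery at scale, from the shell:

```
longgwas benchmark --preset ukb_like -o n_persons=1000 --reps 500 --seed 1
```

prints a type-I-error / power / bias table per approach, and
`longgwas simulate | assoc | scan | followup` cover the rest of the
pipeline (`longgwas --help`).

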