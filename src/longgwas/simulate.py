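"""Synthetic genotypes and longitudinal trait trajectories.

The generative model mirrors the age-interaction mixed model used for
association testing: each person i carries a genotype SNP_i in {0,1,2} drawn
under Hardy-Weinberg proportions, correlated random intercept/slope
deviations (gamma_0i, gamma_1i), and trait values

    y_it = intercept + slope*(age_it - 50) + beta_main*SNP_i
           + beta_decline*(age_it - 50)*SNP_i
           + gamma_0i + gamma_1i*(age_it - 50) + eps_it,

with eps iid N(0, sigma_e^2).  Two presets describe the study designs the
benchmark emulates: ``ukb_like`` (biobank-style irregular visit times,
~50% of persons contributing a single assessment) and ``cohort_like``
(panel-style waves every ~5 years, ~20% singletons, ~20% per-wave
attrition).  Effect units are per year and per effect allele throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, TrajectoryDataset

__all__ = ["ScenarioConfig", "make_scenario", "simulate_genotypes",
           "simulate_trajectories", "simulate_dataset", "permute_null_snps"]


@dataclass
class ScenarioConfig:
    """Parameters of the data-generating model (per-year, trait units)."""

    n_persons: int = 1000
    singleton_fraction: float = 0.5
    visit_scheme: str = "ukb"            # "ukb" irregular or "cohort" waves
    age_first_mean: float = 57.0
    age_first_sd: float = 8.0
    age_first_bounds: tuple[float, float] = (35.0, 78.0)
    mean_extra_visits: float = 4.0       # non-singletons: n_i = 2 + Poisson(mean)
    followup_span: tuple[float, float] = (4.0, 12.0)   # years, uniform
    wave_spacing: float = 5.0            # cohort scheme
    n_waves: int = 5
    attrition: float = 0.2               # cohort scheme, per later wave
    intercept: float = 104.0             # trait level at age 50
    slope: float = -1.0                  # global decline per year
    sd_intercept: float = 12.0
    sd_slope: float = 0.8                # per year
    corr: float = -0.2
    sd_residual: float = 5.0
    beta_main: float = 0.0               # per allele, at age 50
    beta_decline: float = 0.0            # per allele per year
    eaf: float = 0.3
    sex_effect: float = 0.0              # optional; default off
    seed: int | None = None

    def __post_init__(self):
        if min(self.sd_intercept, self.sd_slope, self.sd_residual) < 0:
            raise ValueError("standard deviations must be non-negative")
        if abs(self.corr) > 1:
            raise ValueError("|corr| must be <= 1")
        if not 0 <= self.eaf <= 1:
            raise ValueError("eaf must lie in [0, 1]")
        if not 0 <= self.singleton_fraction <= 1:
            raise ValueError("singleton fraction must lie in [0, 1]")
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")


PRESETS = {
    "ukb_like": {},
    "cohort_like": dict(singleton_fraction=0.2, visit_scheme="cohort",
                        age_first_mean=50.0, age_first_sd=12.0,
                        age_first_bounds=(25.0, 74.0)),
}


def make_scenario(preset: str = "ukb_like", **overrides) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a named preset plus overrides."""
    if preset == "custom":
        base = {}
    elif preset in PRESETS:
        base = dict(PRESETS[preset])
    else:
        raise ValueError(f"unknown preset {preset!r}; choose ukb_like/cohort_like/custom")
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    bad = set(overrides) - known
    if bad:
        raise ValueError(f"unknown override(s): {sorted(bad)}")
    base.update(overrides)
    return ScenarioConfig(**base)


def simulate_genotypes(n: int, eaf: float, seed=None, variant_id: str = "sim1",
                       chrom: str = "1", pos: int = 1) -> GenotypeMatrix:
    """Hard genotypes {0,1,2} under Hardy-Weinberg proportions at the given EAF."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= eaf <= 1:
        raise ValueError("eaf must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, eaf, size=n).astype(float)
    variants = pd.DataFrame([{
        "variant_id": variant_id, "chrom": chrom, "pos": pos,
        "effect_allele": "A", "other_allele": "G", "eaf": eaf}])
    ids = np.array([f"P{i:06d}" for i in range(n)])
    return GenotypeMatrix(variants, g[None, :], ids)


def _visit_ages_flat(cfg: ScenarioConfig, rng):
    """Visit ages for all persons as flat arrays (person codes, ages)."""
    n = cfg.n_persons
    a0 = rng.normal(cfg.age_first_mean, cfg.age_first_sd, size=n)
    lo, hi = cfg.age_first_bounds
    a0 = np.clip(a0, lo, hi)
    singleton = rng.random(n) < cfg.singleton_fraction

    if cfg.visit_scheme == "cohort":
        later = rng.random((n, cfg.n_waves - 1)) >= cfg.attrition
        none_kept = ~later.any(axis=1)
        if none_kept.any():
            forced = rng.integers(cfg.n_waves - 1, size=int(none_kept.sum()))
            later[np.flatnonzero(none_kept), forced] = True
        later[singleton] = False
        counts = 1 + later.sum(axis=1)
        codes = np.repeat(np.arange(n), counts)
        offsets = np.concatenate([
            np.concatenate(([0.0], (np.flatnonzero(row) + 1) * cfg.wave_spacing))
            for row in later])
        return codes, a0[codes] + offsets

    span = rng.uniform(*cfg.followup_span, size=n)
    n_extra = rng.poisson(cfg.mean_extra_visits, size=n)
    counts = np.where(singleton, 1, n_extra + 2)
    codes = np.repeat(np.arange(n), counts)
    # offsets: 0 at first slot, span at last, sorted uniforms in between
    total = counts.sum()
    starts = np.concatenate(([0], np.cumsum(counts)))[:-1]
    pos = np.arange(total) - starts[codes]
    offs = rng.uniform(0.0, 1.0, size=total) * span[codes]
    offs[pos == 0] = 0.0
    last = (pos == counts[codes] - 1) & (counts[codes] > 1)
    offs[last] = span[codes][last]
    order = np.lexsort((offs, codes))
    return codes, a0[codes] + offs[order]


def simulate_trajectories(config: ScenarioConfig, genotypes: GenotypeMatrix,
                          seed=None) -> TrajectoryDataset:
    """Generate trajectories for given genotypes under the scenario model."""
    g = np.asarray(genotypes.dosages[0], dtype=float)
    if len(g) != config.n_persons:
        raise ValueError("genotype length does not match n_persons")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    codes, ages = _visit_ages_flat(config, rng)
    # manual Cholesky factor so zero variances and |corr| = 1 are valid
    L = np.array([
        [config.sd_intercept, 0.0],
        [config.sd_slope * config.corr,
         config.sd_slope * np.sqrt(max(1.0 - config.corr ** 2, 0.0))]])
    gam = rng.standard_normal((config.n_persons, 2)) @ L.T
    sex = rng.integers(0, 2, size=config.n_persons).astype(float)
    x = ages - 50.0
    mu = (config.intercept + config.slope * x
          + config.beta_main * g[codes] + config.beta_decline * x * g[codes]
          + config.sex_effect * sex[codes]
          + gam[codes, 0] + gam[codes, 1] * x)
    vals = mu + (rng.standard_normal(len(x)) * config.sd_residual
                 if config.sd_residual > 0 else 0.0)
    df = pd.DataFrame({
        "person_id": genotypes.person_ids[codes],
        "age": ages,
        "value": vals,
        "sex": sex[codes]})
    return TrajectoryDataset(df)


def simulate_dataset(config: ScenarioConfig, seed=None):
    """Convenience: genotypes + trajectories from independent substreams."""
    root = np.random.default_rng(seed if seed is not None else config.seed)
    s1, s2 = root.integers(0, 2**31 - 1, size=2)
    gm = simulate_genotypes(config.n_persons, config.eaf, seed=int(s1))
    data = simulate_trajectories(config, gm, seed=int(s2))
    return data, gm


def permute_null_snps(genotypes: GenotypeMatrix, n_variants_base: int | None = None,
                      n_permutations: int = 20, seed=None) -> GenotypeMatrix:
    """Null-SNPs by permuting dosages of base variants across persons.

    Each output variant is one of ``n_variants_base`` source variants with its
    dosage vector randomly permuted over persons, repeated ``n_permutations``
    times; allele frequency is exactly preserved per variant.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    nb = n_variants_base if n_variants_base is not None else genotypes.n_variants
    if nb < 1 or nb > genotypes.n_variants:
        raise ValueError("n_variants_base out of range")
    rng = np.random.default_rng(seed)
    n_persons = len(genotypes.person_ids)
    out = np.empty((nb * n_permutations, n_persons))
    meta = []
    k = 0
    for rep in range(n_permutations):
        for v in range(nb):
            out[k] = genotypes.dosages[v, rng.permutation(n_persons)]
            row = genotypes.variants.iloc[v]
            meta.append({**row.to_dict(),
                         "variant_id": f"{row['variant_id']}_perm{rep}"})
            k += 1
    return GenotypeMatrix(pd.DataFrame(meta), out, genotypes.person_ids)
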