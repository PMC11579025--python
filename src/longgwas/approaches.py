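"""Seven approaches to testing genetic association with trait change.

All approaches answer the same question — does an allele alter the per-year
rate of trait change? — and return a uniform :class:`AssociationResult`:

* ``difference`` — per-person (last - first value)/(age span) regressed on
  dosage by ordinary least squares.
* ``time_ri_rs`` — mixed model of the trait over time-since-baseline with
  correlated random intercepts/slopes; decline = time-by-dosage interaction.
* ``age_ri_rs`` / ``age_ri_rs_uncorr`` / ``age_ri_only`` — mixed model over
  age-at-exam with correlated, uncorrelated, or intercept-only random
  structure; decline = age-by-dosage interaction.
* ``blups_linreg`` — two-stage: fit the SNP-free age model, extract BLUP
  slope deviations, regress them on dosage.
* ``age_ri_rs_singletons`` — the age model again, but retaining persons with
  a single assessment (who inform the level but also stabilise the fit).

Effect sizes are reported per effect allele and per year; ``beta_main`` is
the allele effect on the trait level at age 50 (age models) or at baseline
(time model, flagged non-comparable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import TrajectoryDataset
from .lmm import LmmFit, LmmSpec, blup_random_slopes, fit_lmm, wald_test

__all__ = ["AssociationResult", "APPROACHES", "run_approach",
           "run_difference_model", "run_time_model", "run_age_model",
           "run_blups_linreg"]


@dataclass
class AssociationResult:
    """Per-variant association with trait change (and trait level)."""

    variant_id: str
    approach: str
    beta_decline: float
    se_decline: float
    p_decline: float
    beta_main: float | None = None
    se_main: float | None = None
    p_main: float | None = None
    n_persons: int = 0
    m_records: int = 0
    converged: bool = True
    main_comparable: bool = True   # time-model beta_main is baseline-conditioned
    chrom: str | None = None
    pos: int | None = None
    effect_allele: str | None = None
    other_allele: str | None = None
    eaf: float | None = None

    def with_variant_meta(self, row) -> "AssociationResult":
        for k in ("chrom", "pos", "effect_allele", "other_allele", "eaf"):
            setattr(self, k, row[k])
        return self


def _drop_singletons(data: TrajectoryDataset):
    counts = data.n_assessments()
    keep = counts.index[counts >= 2]
    return data.subset_persons(keep)


def _align(data: TrajectoryDataset, dosage, genotype_person_ids):
    """Dosage vector aligned to the dataset's person order."""
    s = pd.Series(np.asarray(dosage, dtype=float), index=np.asarray(genotype_person_ids))
    return s.loc[data.person_ids].to_numpy()


def _ols_normal(y, X, names):
    """OLS with normal-reference Wald p-values; returns dict per coefficient."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return {nm: (float(b), float(s), float(pv)) for nm, b, s, pv in zip(names, beta, se, p)}


def _person_level_design(data: TrajectoryDataset, dosage, covariates):
    base = data.baseline()
    cols = [np.ones(len(base)), np.asarray(dosage, dtype=float)]
    names = ["intercept", "snp"]
    if "sex" in base.columns:
        cols.append(base["sex"].to_numpy(dtype=float))
        names.append("sex")
    for c in covariates:
        cols.append(base[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


def run_difference_model(data: TrajectoryDataset, dosage, genotype_person_ids=None,
                         covariates=(), variant_id: str = "snp") -> AssociationResult:
    """OLS of per-person (last - first)/(age span) on dosage (+ covariates)."""
    data = _drop_singletons(data)
    g = data.table.groupby("person_id")
    first = g.first()
    last = g.last()
    span = (last["age"] - first["age"]).to_numpy()
    if np.any(span <= 0):
        bad = first.index[span <= 0].tolist()[:5]
        raise ValueError(f"zero age span for person(s) {bad}")
    rate = (last["value"] - first["value"]).to_numpy() / span
    if genotype_person_ids is not None:
        dosage = _align(data, dosage, genotype_person_ids)
    X, names = _person_level_design(data, dosage, covariates)
    coefs = _ols_normal(rate, X, names)
    b, se, p = coefs["snp"]
    return AssociationResult(variant_id, "difference", b, se, p,
                             beta_main=None, se_main=None, p_main=None,
                             n_persons=data.n_persons, m_records=2 * data.n_persons,
                             main_comparable=False)


def run_time_model(data: TrajectoryDataset, dosage, genotype_person_ids=None,
                   covariates=(), variant_id: str = "snp") -> AssociationResult:
    """One-stage mixed model over time-since-baseline.

    Singletons carry no within-person time information and are dropped; time
    is coded 0 at each person's first retained assessment.
    """
    data = _drop_singletons(data)
    if data.n_persons < 2:
        raise ValueError("time model requires persons with >= 2 assessments")
    if genotype_person_ids is not None:
        dosage = _align(data, dosage, genotype_person_ids)
    fixed = (["sex"] if data.has_sex() else []) + ["age_baseline", "time", "snp",
                                                  "snp_x_time"]
    if covariates:
        fixed.append("covariates")
    data = TrajectoryDataset(data.table, list(covariates))
    spec = LmmSpec(fixed=fixed, random_structure="RI_RS_correlated", random_slope="time")
    fit = fit_lmm(spec, data, dosage_per_person=dosage)
    b, se, p = wald_test(fit, "snp_x_time")
    bm, sem, pm = wald_test(fit, "snp")
    return AssociationResult(variant_id, "time_ri_rs", b, se, p, bm, sem, pm,
                             n_persons=fit.n_persons, m_records=fit.n_records,
                             converged=fit.converged, main_comparable=False)


def run_age_model(data: TrajectoryDataset, dosage, genotype_person_ids=None,
                  covariates=(), random_structure: str = "RI_RS_correlated",
                  include_singletons: bool = False,
                  variant_id: str = "snp") -> AssociationResult:
    """One-stage mixed model over age-at-exam.

    ``beta_decline`` is the age-by-dosage interaction (per year);
    ``beta_main`` the allele effect on the trait level at age 50.
    """
    if not include_singletons:
        data = _drop_singletons(data)
    if genotype_person_ids is not None:
        dosage = _align(data, dosage, genotype_person_ids)
    fixed = (["sex"] if data.has_sex() else []) + ["age", "snp", "snp_x_age"]
    if covariates:
        fixed.append("covariates")
    data = TrajectoryDataset(data.table, list(covariates))
    spec = LmmSpec(fixed=fixed, random_structure=random_structure, random_slope="age")
    fit = fit_lmm(spec, data, dosage_per_person=dosage)
    b, se, p = wald_test(fit, "snp_x_age")
    bm, sem, pm = wald_test(fit, "snp")
    label = {"RI_RS_correlated": "age_ri_rs",
             "RI_RS_uncorrelated": "age_ri_rs_uncorr",
             "RI_only": "age_ri_only"}[random_structure]
    if include_singletons and label == "age_ri_rs":
        label = "age_ri_rs_singletons"
    return AssociationResult(variant_id, label, b, se, p, bm, sem, pm,
                             n_persons=fit.n_persons, m_records=fit.n_records,
                             converged=fit.converged)


def run_blups_linreg(data: TrajectoryDataset, dosage, genotype_person_ids=None,
                     covariates=(), variant_id: str = "snp",
                     stage1_fit: LmmFit | None = None) -> AssociationResult:
    """Two-stage approach: SNP-free age model -> BLUP slopes -> OLS on dosage.

    ``stage1_fit`` allows reusing one null fit across many variants (the
    stage-1 model has no SNP terms, so it is variant-independent).
    """
    data = _drop_singletons(data)
    if genotype_person_ids is not None:
        dosage = _align(data, dosage, genotype_person_ids)
    data = TrajectoryDataset(data.table, list(covariates))
    if stage1_fit is None:
        fixed = (["sex"] if data.has_sex() else []) + ["age"]
        if covariates:
            fixed.append("covariates")
        spec = LmmSpec(fixed=fixed, random_structure="RI_RS_correlated",
                       random_slope="age")
        stage1_fit = fit_lmm(spec, data)
    if not stage1_fit.converged:
        return AssociationResult(variant_id, "blups_linreg", np.nan, np.nan, np.nan,
                                 n_persons=data.n_persons, m_records=data.n_records,
                                 converged=False)
    slopes = blup_random_slopes(stage1_fit, data).loc[data.person_ids].to_numpy()
    X, names = _person_level_design(data, dosage, covariates)
    coefs = _ols_normal(slopes, X, names)
    b, se, p = coefs["snp"]
    return AssociationResult(variant_id, "blups_linreg", b, se, p,
                             n_persons=data.n_persons, m_records=data.n_records,
                             main_comparable=False)


APPROACHES = {
    "difference": run_difference_model,
    "time_ri_rs": run_time_model,
    "age_ri_rs": lambda d, g, ids=None, covariates=(), variant_id="snp":
        run_age_model(d, g, ids, covariates, "RI_RS_correlated", False, variant_id),
    "age_ri_rs_uncorr": lambda d, g, ids=None, covariates=(), variant_id="snp":
        run_age_model(d, g, ids, covariates, "RI_RS_uncorrelated", False, variant_id),
    "age_ri_only": lambda d, g, ids=None, covariates=(), variant_id="snp":
        run_age_model(d, g, ids, covariates, "RI_only", False, variant_id),
    "blups_linreg": run_blups_linreg,
    "age_ri_rs_singletons": lambda d, g, ids=None, covariates=(), variant_id="snp":
        run_age_model(d, g, ids, covariates, "RI_RS_correlated", True, variant_id),
}


def run_approach(name: str, data: TrajectoryDataset, dosage,
                 genotype_person_ids=None, covariates=(),
                 variant_id: str = "snp") -> AssociationResult:
    """Dispatch one of the seven approaches by name."""
    if name not in APPROACHES:
        raise ValueError(f"unknown approach {name!r}; choose from {sorted(APPROACHES)}")
    return APPROACHES[name](data, dosage, genotype_person_ids,
                            covariates=covariates, variant_id=variant_id)
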