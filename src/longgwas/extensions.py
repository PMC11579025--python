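"""Follow-up analyses around the decline association framework.

Non-linear age effects (quadratic and breakpoint/hinge terms), a
location-scale screen for trait-variability association, age-dependent
allele effect curves, classification of "stable-effect" variants (strong
age-independent level effect, no decline effect), exact binomial enrichment
tests, clinical progression traits (rapid decline, decline within CKD, CKD
case/control), and a decline polygenic score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .approaches import AssociationResult, run_age_model, _align
from .data import TrajectoryDataset
from .lmm import LmmSpec, blup_random_slopes, fit_lmm, wald_test

__all__ = ["EffectCurve", "fit_quadratic_terms", "fit_breakpoint_model",
           "fit_location_scale", "age_effect_curve", "classify_stable_effect",
           "enrichment_test", "define_rapid_decline", "rapid_decline_logistic",
           "prepare_ckd_subset", "ckd_ever_logistic", "build_pgs", "test_pgs"]


# ---------------------------------------------------------------------------
# non-linear age effects
# ---------------------------------------------------------------------------

QUADRATIC_TERMS = ("global_age2", "random_age2", "snp_x_age2")


def _age_model_fixed(data, covariates):
    fixed = (["sex"] if data.has_sex() else []) + ["age", "snp", "snp_x_age"]
    if covariates:
        fixed.append("covariates")
    return fixed


def fit_quadratic_terms(data: TrajectoryDataset, dosage, genotype_person_ids=None,
                        covariates=(), which: str = "snp_x_age2") -> dict:
    """Augment the age model RI&RS with a quadratic age term.

    ``which`` selects the augmentation: ``global_age2`` (population-level
    curvature), ``random_age2`` (person-specific curvature in the random
    part), or ``snp_x_age2`` (allele-dependent curvature).  Returns the
    linear decline estimate with and without the augmentation and, where a
    fixed quadratic term is added, its Wald p-value.
    """
    if which not in QUADRATIC_TERMS:
        raise ValueError(f"unknown term {which!r}; choose from {QUADRATIC_TERMS}")
    if genotype_person_ids is not None:
        dosage = _align(data, dosage, genotype_person_ids)
    data = TrajectoryDataset(data.table, list(covariates))
    base_spec = LmmSpec(fixed=_age_model_fixed(data, covariates),
                        random_structure="RI_RS_correlated", random_slope="age")
    base = fit_lmm(base_spec, data, dosage_per_person=dosage)

    fixed = list(base_spec.fixed)
    extra_random: list[str] = []
    added = None
    if which == "global_age2":
        fixed = fixed[:fixed.index("snp")] + ["age2"] + fixed[fixed.index("snp"):]
        added = "age2"
    elif which == "snp_x_age2":
        fixed = fixed + ["snp_x_age2"]
        added = "snp_x_age2"
    else:  # random_age2: quadratic person-specific deviation
        extra_random = ["age2"]
    aug_spec = LmmSpec(fixed=fixed, random_structure="RI_RS_correlated",
                       random_slope="age", extra_random_terms=extra_random)
    aug = fit_lmm(aug_spec, data, dosage_per_person=dosage)

    b0, se0, p0 = wald_test(base, "snp_x_age")
    b1, se1, p1 = wald_test(aug, "snp_x_age")
    out = {"beta_decline_base": b0, "se_base": se0, "p_decline_base": p0,
           "beta_decline_augmented": b1, "se_augmented": se1,
           "p_decline_augmented": p1, "term": which,
           "converged": base.converged and aug.converged,
           "fit_base": base, "fit_augmented": aug}
    if added is not None:
        bq, seq, pq = wald_test(aug, added)
        out.update(beta_term=bq, se_term=seq, p_term=pq)
    return out


def fit_breakpoint_model(data: TrajectoryDataset, dosage, genotype_person_ids=None,
                         covariates=(), knot: float = 50.0) -> dict:
    """Piecewise-linear (hinge) allele-by-age model with a knot at 40/50/60 y.

    Adds (age - knot)_+ to both the global age term and the allele
    interaction; ``p_breakpoint`` is the Wald p of the allele hinge term,
    and the per-segment allele slopes are the interaction coefficient before
    the knot and its sum with the hinge coefficient after it.
    """
    ages = data.table["age"]
    if not (ages.min() < knot < ages.max()):
        raise ValueError(f"knot {knot} outside observed age range "
                         f"[{ages.min():.1f}, {ages.max():.1f}]")
    if genotype_person_ids is not None:
        dosage = _align(data, dosage, genotype_person_ids)
    data = TrajectoryDataset(data.table, list(covariates))
    hinge, shinge = f"hinge{knot:g}", f"snp_x_hinge{knot:g}"
    fixed = (["sex"] if data.has_sex() else []) + \
        ["age", hinge, "snp", "snp_x_age", shinge]
    if covariates:
        fixed.append("covariates")
    spec = LmmSpec(fixed=fixed, random_structure="RI_RS_correlated",
                   random_slope="age")
    fit = fit_lmm(spec, data, dosage_per_person=dosage)
    bh, seh, ph = wald_test(fit, shinge)
    b1, _, _ = wald_test(fit, "snp_x_age")
    return {"knot": knot, "p_breakpoint": ph, "beta_hinge": bh, "se_hinge": seh,
            "slope_before": b1, "slope_after": b1 + bh, "converged": fit.converged,
            "fit": fit}


# ---------------------------------------------------------------------------
# location-scale (variability) model
# ---------------------------------------------------------------------------

def fit_location_scale(data: TrajectoryDataset, dosage, genotype_person_ids=None,
                       covariates=(), scale_terms: str = "full",
                       max_iter: int = 200) -> dict:
    """Gaussian location-scale screen for allele effects on trait variability.

    Records are treated as independent: mean mu = X beta and log standard
    deviation log sigma = W alpha, with X and W both [1, sex, age, SNP,
    covariates] (``scale_terms="intercept"`` restricts W to the intercept,
    which reproduces homoscedastic maximum likelihood).  Reports the allele
    coefficient on log sigma (``alpha_snp``) and its Wald p.  This screens a
    different question than association with trait change; decline inference
    belongs to the mixed models.
    """
    if genotype_person_ids is not None:
        dosage = _align(data, dosage, genotype_person_ids)
    df = data.table
    codes, _ = pd.factorize(df["person_id"], sort=False)
    g_rec = np.asarray(dosage, dtype=float)[codes]
    x_age = (df["age"].to_numpy() - 50.0) / 10.0
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if "sex" in df.columns:
        cols.append(df["sex"].to_numpy(float)); names.append("sex")
    cols += [x_age, g_rec]
    names += ["age", "snp"]
    for c in covariates:
        cols.append(df[c].to_numpy(float)); names.append(c)
    X = np.column_stack(cols)
    W = X if scale_terms == "full" else X[:, :1]
    wnames = names if scale_terms == "full" else ["intercept"]
    y = df["value"].to_numpy(float)
    p, q = X.shape[1], W.shape[1]

    def nll(par):
        beta, alpha = par[:p], par[p:]
        eta = W @ alpha
        eta = np.clip(eta, -30, 30)
        r = y - X @ beta
        return float(np.sum(eta + 0.5 * (r * np.exp(-eta)) ** 2)) \
            + 0.5 * len(y) * np.log(2 * np.pi)

    def grad(par):
        beta, alpha = par[:p], par[p:]
        eta = np.clip(W @ alpha, -30, 30)
        inv_var = np.exp(-2 * eta)
        r = y - X @ beta
        gb = -(X.T @ (r * inv_var))
        ga = W.T @ (1.0 - r * r * inv_var)
        return np.concatenate([gb, ga])

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    s0 = np.log(np.std(y - X @ beta0))
    x0 = np.concatenate([beta0, [s0] + [0.0] * (q - 1)])
    res = optimize.minimize(nll, x0, jac=grad, method="L-BFGS-B",
                            options={"maxiter": max_iter, "ftol": 1e-12})
    beta, alpha = res.x[:p], res.x[p:]
    # observed-information SEs via numerical Hessian of the analytic gradient
    hess = _numeric_jacobian(grad, res.x)
    cov = np.linalg.inv(0.5 * (hess + hess.T))
    se = np.sqrt(np.diag(cov))
    out = {"beta": dict(zip(names, beta)), "alpha": dict(zip(wnames, alpha)),
           "se_beta": dict(zip(names, se[:p])), "se_alpha": dict(zip(wnames, se[p:])),
           "converged": bool(res.success), "loglik": -res.fun}
    if "snp" in wnames:
        i = p + wnames.index("snp")
        z = res.x[i] / se[i]
        out.update(alpha_snp=float(res.x[i]), se_alpha_snp=float(se[i]),
                   p_alpha_snp=float(2 * stats.norm.sf(abs(z))))
    return out


def _numeric_jacobian(f, x, eps=1e-5):
    n = len(x)
    J = np.empty((n, n))
    for j in range(n):
        step = np.zeros(n)
        step[j] = eps * max(1.0, abs(x[j]))
        J[:, j] = (f(x + step) - f(x - step)) / (2 * step[j])
    return J


# ---------------------------------------------------------------------------
# effect curves, classification, enrichment
# ---------------------------------------------------------------------------

@dataclass
class EffectCurve:
    """Allele effect on trait level as a linear function of age."""

    ages: np.ndarray
    effects: np.ndarray
    beta_main: float
    beta_decline: float


def age_effect_curve(beta_main: float, beta_decline: float, ages) -> EffectCurve:
    """effect(age) = beta_main + (age - 50) * beta_decline."""
    ages = np.asarray(ages, dtype=float)
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    return EffectCurve(ages, beta_main + (ages - 50.0) * beta_decline,
                       beta_main, beta_decline)


def classify_stable_effect(result: AssociationResult,
                           p_main_max: float = 5e-8,
                           beta_main_min: float = 0.50,
                           p_decline_min: float = 0.1,
                           beta_decline_max: float = 0.005,
                           se_decline_max: float = 0.005) -> bool:
    """Stable-effect variant: strong level effect, no detectable decline effect.

    True iff p_main < 5e-8, |beta_main| > 0.50, p_decline >= 0.1,
    |beta_decline| < 0.005 and SE_decline < 0.005 (trait units per allele,
    decline per allele per year).
    """
    for f in ("p_main", "beta_main", "p_decline", "beta_decline", "se_decline"):
        v = getattr(result, f)
        if v is None or not np.isfinite(v):
            raise ValueError(f"result lacks field {f!r}")
    return bool(result.p_main < p_main_max
                and abs(result.beta_main) > beta_main_min
                and result.p_decline >= p_decline_min
                and abs(result.beta_decline) < beta_decline_max
                and result.se_decline < se_decline_max)


def enrichment_test(k: int, n: int, p0: float = 0.05) -> float:
    """One-sided exact binomial upper-tail P(X >= k), X ~ Binomial(n, p0).

    The null probability defaults to 0.05: each variant independently has a
    5% chance of a directionally consistent nominally significant result.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    return float(stats.binom.sf(k - 1, n, p0))


# ---------------------------------------------------------------------------
# clinical progression traits
# ---------------------------------------------------------------------------

def define_rapid_decline(data: TrajectoryDataset, null_fit,
                         case_threshold: float = -3.0,
                         control_range: tuple[float, float] = (-1.0, 1.0)
                         ) -> pd.Series:
    """Person-level labels from BLUP-estimated annual decline.

    Person-specific slope = global age slope + BLUP deviation (per year);
    cases decline faster than -3/year, controls lie within [-1, +1]/year,
    everyone else is unlabeled (NaN).  ``null_fit`` must be the SNP-free age
    model RI&RS fitted to the same data.
    """
    if null_fit.spec.random_structure == "RI_only":
        raise ValueError("rapid-decline labels need a random-slope model")
    slopes = blup_random_slopes(null_fit, data)
    global_slope, _ = null_fit.coef("age")
    total = slopes + global_slope
    labels = pd.Series(np.nan, index=total.index, name="rapid_decline")
    labels[total < case_threshold] = 1.0
    labels[(total >= control_range[0]) & (total <= control_range[1])] = 0.0
    return labels


def rapid_decline_logistic(labels: pd.Series, data: TrajectoryDataset, dosage,
                           genotype_person_ids=None, covariates=()) -> dict:
    """Per-variant logistic regression of case/control on dosage.

    Adjusted for age-at-baseline, sex and covariates; unlabeled persons are
    excluded.
    """
    import statsmodels.api as sm

    base = data.baseline().set_index("person_id")
    lab = labels.dropna()
    base = base.loc[lab.index]
    if genotype_person_ids is not None:
        g = pd.Series(np.asarray(dosage, float),
                      index=np.asarray(genotype_person_ids)).loc[lab.index].to_numpy()
    else:
        g = np.asarray(dosage, float)
    cols = {"snp": g, "age_baseline": base["age"].to_numpy()}
    if "sex" in base.columns:
        cols["sex"] = base["sex"].to_numpy()
    for c in covariates:
        cols[c] = base[c].to_numpy()
    X = sm.add_constant(pd.DataFrame(cols, index=lab.index))
    model = sm.Logit(lab.astype(float), X)
    fit = model.fit(disp=0)
    return {"beta": float(fit.params["snp"]), "se": float(fit.bse["snp"]),
            "p": float(fit.pvalues["snp"]), "odds_ratio": float(np.exp(fit.params["snp"])),
            "n_cases": int(lab.sum()), "n_controls": int((lab == 0).sum())}


def prepare_ckd_subset(data: TrajectoryDataset, threshold: float = 60.0
                       ) -> tuple[TrajectoryDataset, pd.Series]:
    """Trajectories restricted to the chronic-kidney-disease phase.

    Keeps persons with at least one value below ``threshold`` and, within
    them, drops records before the first sub-threshold value — the first
    retained timepoint is therefore informative, so decline testing in this
    subset should use the time model RI&RS.  Also returns CKD-ever labels
    (1/0) for every person for case/control analysis.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    df = data.table
    below = df["value"] < threshold
    ever = below.groupby(df["person_id"]).any()
    labels = ever.astype(float).rename("ckd_ever")
    at_or_after = below.groupby(df["person_id"]).cummax()
    sub = df.loc[at_or_after].reset_index(drop=True)
    subset = TrajectoryDataset(sub, list(data.covariate_cols))
    return subset, labels


def ckd_ever_logistic(labels: pd.Series, data: TrajectoryDataset, dosage,
                      genotype_person_ids=None, covariates=()) -> dict:
    """Logistic regression of CKD-ever status on dosage (sex/age-adjusted)."""
    return rapid_decline_logistic(labels, data, dosage, genotype_person_ids,
                                  covariates)


# ---------------------------------------------------------------------------
# polygenic score
# ---------------------------------------------------------------------------

def build_pgs(weights: pd.DataFrame, genotypes) -> pd.Series:
    """Per-person decline polygenic score: sum of weight * dosage.

    ``weights`` must carry ``variant_id``, ``effect_allele`` and ``weight``
    (the per-allele decline effect); alleles are checked against the
    genotype metadata and mismatches raise.
    """
    score = np.zeros(len(genotypes.person_ids))
    meta = genotypes.variants.set_index("variant_id")
    for _, row in weights.iterrows():
        vid = row["variant_id"]
        if vid not in meta.index:
            raise KeyError(f"variant {vid!r} absent from genotypes")
        if row["effect_allele"] != meta.loc[vid, "effect_allele"]:
            raise ValueError(f"effect-allele mismatch for {vid!r}: "
                             f"{row['effect_allele']} vs {meta.loc[vid, 'effect_allele']}")
        score += row["weight"] * genotypes.dosage_for(vid)
    return pd.Series(score, index=genotypes.person_ids, name="pgs")


def test_pgs(score: pd.Series, data: TrajectoryDataset,
             covariates=()) -> AssociationResult:
    """Test the score for decline association via the age model with singletons.

    The score plays the role of the dosage column; study-membership
    indicators belong in ``covariates``.
    """
    if np.allclose(score.to_numpy(), score.iloc[0]):
        raise ValueError("degenerate score: no variation across persons")
    return run_age_model(data, score.to_numpy(), score.index.to_numpy(),
                         covariates=covariates, include_singletons=True,
                         variant_id="pgs")
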