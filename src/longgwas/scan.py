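"""Efficient genome-wide scan for allele-by-age interaction.

Refitting a mixed model per variant is infeasible at genome scale.  Instead,
the phenotypic variance-covariance is estimated once from the SNP-free age
model ("null model"); each variant is then evaluated with a score test that
reuses the null fit.  For a dosage column G (per person, constant across a
person's records) and its age interaction K = G * (age - 50), the joint score
vector is U = [G, K]' P y with P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1.  The
decline test conditions the interaction score on the main-effect score,

    U_{K|G} = U_K - S_KG S_GG^-1 U_G,   Var = S_KK - S_KG S_GG^-1 S_GK,

and refers U_{K|G}^2 / Var to chi-square(1).  Because both columns are, per
person, the dosage times the random-effect design [1, age-scaled], all
quadratic forms reduce to cached per-person 2x2/2xp blocks, giving O(records)
cost for the null fit and O(persons) per variant.

Residual inflation is corrected by genomic control: lambda = median(chi2) /
0.4549 (the median of chi-square(1)); significant variants are grouped into
loci by +/-250 kb clumping with overlapping loci merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from scipy import optimize

from .data import GenotypeMatrix, TrajectoryDataset
from .lmm import (LmmFit, LmmSpec, _ProfiledREML, _design_arrays,
                  _theta_from_params, fit_lmm)

__all__ = ["NullModelFit", "ScanResult", "fit_null_model", "score_test_variant",
           "scan_variants", "genomic_control", "clump_loci"]

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...
GENOMEWIDE_P = 5e-8


@dataclass
class NullModelFit:
    """SNP-free age-model fit plus cached per-person projection blocks."""

    fit: LmmFit
    person_ids: np.ndarray
    u: np.ndarray        # (n, 2)   Z_i' W^-1 (y_i - X_i beta)
    B: np.ndarray        # (n, 2, 2) Z_i' W^-1 Z_i
    C: np.ndarray        # (n, 2, p) Z_i' W^-1 X_i
    XtWX_inv: np.ndarray
    sigma2: float
    theta_params: np.ndarray | None = None   # log-Cholesky of the null Theta


@dataclass
class ScanResult:
    table: pd.DataFrame       # per-variant statistics
    lambda_gc: float
    loci: pd.DataFrame | None = None


def fit_null_model(data: TrajectoryDataset, covariates=(),
                   spec: LmmSpec | None = None) -> NullModelFit:
    """Fit the SNP-free age model RI&RS once and cache projection components."""
    data = TrajectoryDataset(data.table, list(covariates))
    if spec is None:
        fixed = (["sex"] if data.has_sex() else []) + ["age"]
        if covariates:
            fixed.append("covariates")
        spec = LmmSpec(fixed=fixed, random_structure="RI_RS_correlated",
                       random_slope="age")
    if spec.random_structure != "RI_RS_correlated" or any(
            t.startswith("snp") for t in spec.fixed):
        raise ValueError("null model must be the SNP-free age model RI&RS")
    fit = fit_lmm(spec, data)
    if not fit.converged:
        raise RuntimeError("null model did not converge; scan aborted")

    y, X, Z, codes, _ = _design_arrays(spec, data, None)
    prob = fit._cache["prob"]
    A = fit._cache["A"]                      # (n, q, q), q = 2
    ZtZ, ZtX, Zty = prob.ZtZ, prob.ZtX, prob.Zty
    # Z' W^-1 M  =  Z'M - Z'Z A Z'M  for any M with cached Z'M
    B = ZtZ - np.einsum("nab,nbc,ncd->nad", ZtZ, A, ZtZ)
    C = ZtX - np.einsum("nab,nbc,ncp->nap", ZtZ, A, ZtX)
    resid_t = Zty - np.einsum("nap,p->na", ZtX, fit.beta_internal)
    u = resid_t - np.einsum("nab,nbc,nc->na", ZtZ, A, resid_t)
    XtWX_inv = np.linalg.inv(fit._cache["XtWX"])
    ids = data.table.loc[~data.table["person_id"].duplicated(), "person_id"].to_numpy()
    L = np.linalg.cholesky(fit.theta_internal + 1e-12 * np.eye(2))
    theta_params = np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])
    return NullModelFit(fit=fit, person_ids=ids, u=u, B=B, C=C,
                        XtWX_inv=XtWX_inv, sigma2=fit.sigma2_residual,
                        theta_params=theta_params)


def score_test_variant(null: NullModelFit, dosages,
                       refine_p: float | None = 0.05) -> dict:
    """Joint main/interaction score test of one variant against the null fit.

    Returns a dict with chi2/p for the decline (interaction conditioned on the
    main effect) and the main-effect test, plus the score-based effect
    approximation ``beta_decline`` = U_{K|G}/Var (per year).

    Variants whose initial score p falls below ``refine_p`` get a second-stage
    exact Wald test from a warm-started REML refit of the augmented model: the
    plain score holds the variance components at the null estimate, which
    slightly misstates the tail statistic because a true (or chance) allele
    effect absorbs part of the slope variance.  The refit is assembled from
    the cached per-person cross-products, so it stays O(records) per refined
    variant; pass ``refine_p=None`` for the pure one-pass score test.
    """
    g = np.asarray(dosages, dtype=float)
    if g.shape != (len(null.person_ids),):
        raise ValueError("dosage vector length must equal number of persons")
    if np.ptp(g) == 0:
        return {"monomorphic": True, "chi2_decline": np.nan, "p_decline": np.nan,
                "chi2_main": np.nan, "p_main": np.nan, "beta_decline": np.nan,
                "refined": False}
    U = g @ null.u / null.sigma2                                  # (2,)
    Bg = np.einsum("n,nab->ab", g * g, null.B)
    Cg = np.einsum("n,nap->ap", g, null.C)
    S = (Bg - Cg @ null.XtWX_inv @ Cg.T) / null.sigma2
    chi2_main = U[0] ** 2 / S[0, 0]
    u_c = U[1] - S[1, 0] / S[0, 0] * U[0]
    v_c = S[1, 1] - S[1, 0] ** 2 / S[0, 0]
    chi2_dec = u_c ** 2 / v_c
    beta_internal = u_c / v_c   # score-based effect estimate, internal axis
    out = {"monomorphic": False,
           "chi2_decline": float(chi2_dec),
           "p_decline": float(stats.chi2.sf(chi2_dec, 1)),
           "chi2_main": float(chi2_main),
           "p_main": float(stats.chi2.sf(chi2_main, 1)),
           "beta_decline": float(beta_internal / null.fit.spec.scale),
           "refined": False}
    if refine_p is not None and out["p_decline"] < refine_p:
        out.update(_refined_wald(null, g))
        out["refined"] = True
    return out


def _augmented_problem(null: NullModelFit, g: np.ndarray) -> _ProfiledREML:
    """REML problem for the null design plus [G, G*age] columns, from caches.

    Per person, the two added columns equal the dosage times the random-effect
    design [1, age_scaled], so every cross-product with them reduces to a
    dosage-weighted sum of cached blocks; nothing touches the raw records.
    """
    prob = null.fit._cache["prob"]
    aug = _ProfiledREML.__new__(_ProfiledREML)
    aug.ZtZ = prob.ZtZ
    aug.Zty = prob.Zty
    aug.ZtX = np.concatenate([prob.ZtX, prob.ZtZ * g[:, None, None]], axis=2)
    p = prob.p
    XtX = np.empty((p + 2, p + 2))
    XtX[:p, :p] = prob.XtX
    XtC = np.einsum("n,nap->pa", g, prob.ZtX)          # (p, 2): X'[G, K]
    XtX[:p, p:] = XtC
    XtX[p:, :p] = XtC.T
    XtX[p:, p:] = np.einsum("n,nab->ab", g * g, prob.ZtZ)
    aug.XtX = XtX
    aug.Xty = np.concatenate([prob.Xty, g @ prob.Zty])
    aug.yty = prob.yty
    aug.N, aug.p = prob.N, p + 2
    aug.q = prob.q
    aug.method = null.fit.spec.method
    return aug


def _refined_wald(null: NullModelFit, g: np.ndarray) -> dict:
    """Exact REML Wald for main/interaction, warm-started at the null theta."""
    aug = _augmented_problem(null, g)
    structure = null.fit.spec.random_structure

    def obj(par):
        return aug.objective(par, structure)

    res = optimize.minimize(obj, null.theta_params, method="L-BFGS-B",
                            options={"maxiter": 200, "ftol": 1e-10})
    theta = _theta_from_params(res.x, aug.q, structure)
    comp = aug.components(theta)
    if comp is None:
        return {}
    _, XtWX, _, beta, r2, _ = comp
    sigma2 = r2 / (aug.N - aug.p)
    cov = sigma2 * np.linalg.inv(XtWX)
    iG, iK = aug.p - 2, aug.p - 1
    zK2 = beta[iK] ** 2 / cov[iK, iK]
    zG2 = beta[iG] ** 2 / cov[iG, iG]
    return {"chi2_decline": float(zK2),
            "p_decline": float(stats.chi2.sf(zK2, 1)),
            "chi2_main": float(zG2),
            "p_main": float(stats.chi2.sf(zG2, 1)),
            "beta_decline": float(beta[iK] / null.fit.spec.scale)}


def scan_variants(null: NullModelFit, genotypes: GenotypeMatrix,
                  maf_min: float = 0.005, gc_correct: bool = True,
                  clump: bool = False, significance: float = GENOMEWIDE_P,
                  half_window: int = 250_000) -> ScanResult:
    """Score-test every variant, apply genomic control, optionally clump loci.

    Variants with MAF below ``maf_min`` (0.5% by default) are skipped.
    GC correction applies to the decline test only; the main-effect p-value is
    reported uncorrected.
    """
    dosages = genotypes.aligned_to(null.person_ids)
    rows = []
    for v in range(genotypes.n_variants):
        meta = genotypes.variants.iloc[v]
        eaf = np.nanmean(dosages[v]) / 2.0
        maf = min(eaf, 1.0 - eaf)
        if maf < maf_min:
            continue
        r = score_test_variant(null, dosages[v])
        rows.append({"variant_id": meta["variant_id"], "chrom": meta["chrom"],
                     "pos": meta["pos"], "eaf": eaf, **r})
    table = pd.DataFrame(rows)
    lam = 1.0
    if gc_correct and len(table):
        lam, p_corr = genomic_control(table["chi2_decline"].to_numpy())
        table["lambda_gc"] = lam
        table["p_decline_gc"] = p_corr
    elif len(table):
        table["lambda_gc"] = np.nan
        table["p_decline_gc"] = table["p_decline"]
    result = ScanResult(table=table, lambda_gc=lam)
    if clump and len(table):
        result.loci = clump_loci(result, significance, half_window)
    return result


def genomic_control(chisq) -> tuple[float, np.ndarray]:
    """Genomic-control inflation factor and corrected p-values.

    lambda = median(chi2) / median of chi-square(1); corrected p is the upper
    tail probability of chi2 / lambda.
    """
    chisq = np.asarray(chisq, dtype=float)
    chisq = chisq[np.isfinite(chisq)]
    if chisq.size == 0:
        raise ValueError("no test statistics supplied")
    lam = float(np.median(chisq) / CHI2_1_MEDIAN)
    p_corr = stats.chi2.sf(chisq / lam, 1)
    return lam, p_corr


def clump_loci(scan: ScanResult, significance: float = GENOMEWIDE_P,
               half_window: int = 250_000) -> pd.DataFrame:
    """Greedy distance-based clumping of significant variants into loci.

    Repeatedly take the unassigned significant variant with the smallest
    GC-corrected p (ties broken by chrom, pos) as a locus lead spanning
    lead +/- ``half_window``; overlapping loci on a chromosome are merged so
    distinct loci are more than 2*half_window apart.
    """
    t = scan.table
    if "pos" not in t.columns or t["pos"].isna().any():
        raise ValueError("variant positions required for clumping")
    sig = t[t["p_decline_gc"] < significance].copy()
    sig = sig.sort_values(["p_decline_gc", "chrom", "pos"], kind="stable")
    loci = []
    assigned = np.zeros(len(sig), dtype=bool)
    pos = sig["pos"].to_numpy()
    chrom = sig["chrom"].to_numpy()
    for i in range(len(sig)):
        if assigned[i]:
            continue
        lead = sig.iloc[i]
        within = (~assigned) & (chrom == lead["chrom"]) & \
                 (np.abs(pos - lead["pos"]) <= half_window)
        assigned |= within
        loci.append({"chrom": lead["chrom"], "start": int(lead["pos"]) - half_window,
                     "end": int(lead["pos"]) + half_window,
                     "lead_variant": lead["variant_id"],
                     "lead_p": float(lead["p_decline_gc"]),
                     "n_variants": int(within.sum())})
    df = pd.DataFrame(loci)
    if df.empty:
        return df
    # merge overlapping loci per chromosome
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    merged = []
    for _, row in df.iterrows():
        if merged and row["chrom"] == merged[-1]["chrom"] and \
                row["start"] <= merged[-1]["end"]:
            prev = merged[-1]
            prev["end"] = max(prev["end"], row["end"])
            prev["n_variants"] += row["n_variants"]
            if row["lead_p"] < prev["lead_p"]:
                prev["lead_variant"], prev["lead_p"] = row["lead_variant"], row["lead_p"]
        else:
            merged.append(row.to_dict())
    out = pd.DataFrame(merged)
    out["start"] = out["start"].clip(lower=0)
    return out.reset_index(drop=True)
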