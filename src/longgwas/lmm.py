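"""REML/ML estimation of linear mixed models with per-person random effects.

The models fitted here are the workhorses of longitudinal GWAS on trait
change: a trait measured repeatedly per person is modelled with fixed effects
(sex, age or time-since-baseline, allele dosage, dosage-by-age interaction,
covariates) and per-person random intercepts and slopes,

    y_it = x_it' beta + gamma_0i + gamma_1i * s_it + eps_it,

with (gamma_0i, gamma_1i) bivariate normal with covariance D, eps iid
N(0, sigma_e^2) and s the random-slope variable (age or time).  Estimation
profiles beta and sigma_e^2 out of the (restricted) likelihood and optimizes
the remaining relative-covariance parameters Theta = D / sigma_e^2 under a
log-Cholesky parameterization, so D is positive semidefinite by construction.

All computations are block-wise per person: only per-person cross-products
Z_i'Z_i, Z_i'X_i, Z_i'y_i enter each likelihood evaluation, giving cost
linear in the total number of records.  Internally the age axis is rescaled
to (age - 50) / 10 (and time to time / 10) for well-conditioned optimization;
all reported effects and variance components are back-transformed to
per-year units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import TrajectoryDataset

__all__ = ["LmmSpec", "LmmFit", "fit_lmm", "blup_random_slopes", "wald_test",
           "build_design", "AGE_CENTER", "AGE_SCALE"]

AGE_CENTER = 50.0
AGE_SCALE = 10.0

RANDOM_STRUCTURES = ("RI_RS_correlated", "RI_RS_uncorrelated", "RI_only")


@dataclass
class LmmSpec:
    """Model specification.

    ``fixed`` lists fixed-effect terms by name: any of ``sex``, ``age``,
    ``time``, ``age_baseline``, ``snp``, ``snp_x_age``, ``snp_x_time``,
    ``age2``, ``snp_x_age2``, ``covariates``, or ``hinge<k>``/``snp_x_hinge<k>``
    for breakpoint terms with knot ``<k>`` years.  The random-slope variable
    must appear among the fixed terms.
    """

    fixed: list[str]
    random_structure: str = "RI_RS_correlated"
    random_slope: str = "age"          # "age" or "time"
    extra_random_terms: list[str] = field(default_factory=list)  # e.g. ["age2"]
    method: str = "REML"               # or "ML"
    center: float = AGE_CENTER
    scale: float = AGE_SCALE

    def __post_init__(self):
        if self.random_structure not in RANDOM_STRUCTURES:
            raise ValueError(f"unknown random structure {self.random_structure!r}")
        if self.random_structure != "RI_only" and self.random_slope not in self.fixed:
            raise ValueError("random-slope variable must be among the fixed terms")
        if self.method not in ("REML", "ML"):
            raise ValueError("method must be REML or ML")


@dataclass
class LmmFit:
    """A fitted linear mixed model.

    Fixed effects are reported on the internal (scaled) axis in
    ``beta_internal`` and on the natural per-year scale in ``beta``;
    ``fixed_names`` indexes both.  Variance components are on the per-year
    scale: ``sd_intercept``, ``sd_slope`` (per year), ``corr`` and
    ``sigma2_residual``.
    """

    spec: LmmSpec
    fixed_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    beta_internal: np.ndarray
    cov_beta_internal: np.ndarray
    sd_intercept: float
    sd_slope: float | None
    corr: float | None
    sigma2_residual: float
    loglik: float
    converged: bool
    boundary: bool
    n_iter: int
    n_persons: int
    n_records: int
    theta_internal: np.ndarray          # Theta = D/sigma2 on internal scale (q,q)
    _cache: dict = field(default_factory=dict, repr=False)

    def coef(self, name: str) -> tuple[float, float]:
        """(estimate, SE) for a fixed effect on the per-year scale."""
        if name not in self.fixed_names:
            raise KeyError(f"unknown coefficient {name!r}; have {self.fixed_names}")
        i = self.fixed_names.index(name)
        return float(self.beta[i]), float(self.se[i])

    def conditional_residuals(self, data: TrajectoryDataset) -> np.ndarray:
        """y - X beta - Z gamma_hat, in table row order."""
        y, X, Z, codes, _ = _design_arrays(self.spec, data, self._cache.get("dosage"))
        gam = _blups_internal(self, codes.max() + 1, Z, X, y, codes)
        return y - X @ self.beta_internal - np.einsum("ij,ij->i", Z, gam[codes])


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(spec: LmmSpec, data: TrajectoryDataset, dosage_per_person=None):
    """Build (y, X, Z, person_codes, fixed_names) for a spec.

    ``dosage_per_person`` is aligned to ``data.person_ids`` order.
    """
    return _design_arrays(spec, data, dosage_per_person, with_names=True)


def _design_arrays(spec, data, dosage_per_person, with_names=False):
    df = data.table
    codes, uniques = pd.factorize(df["person_id"], sort=False)
    x_age = (df["age"].to_numpy() - spec.center) / spec.scale
    x_time = df["time"].to_numpy() / spec.scale
    age1 = df.groupby("person_id")["age"].transform("first").to_numpy()
    x_age1 = (age1 - spec.center) / spec.scale
    g_rec = None
    if dosage_per_person is not None:
        g_rec = np.asarray(dosage_per_person, dtype=float)[codes]

    def term(name):
        if name == "sex":
            return df["sex"].to_numpy(dtype=float)
        if name == "age":
            return x_age
        if name == "time":
            return x_time
        if name == "age_baseline":
            return x_age1
        if name == "age2":
            return x_age ** 2
        if name == "snp":
            return g_rec
        if name == "snp_x_age":
            return g_rec * x_age
        if name == "snp_x_time":
            return g_rec * x_time
        if name == "snp_x_age2":
            return g_rec * x_age ** 2
        if name.startswith("snp_x_hinge"):
            knot = (float(name[len("snp_x_hinge"):]) - spec.center) / spec.scale
            return g_rec * np.maximum(x_age - knot, 0.0)
        if name.startswith("hinge"):
            knot = (float(name[len("hinge"):]) - spec.center) / spec.scale
            return np.maximum(x_age - knot, 0.0)
        if name in df.columns:
            return df[name].to_numpy(dtype=float)
        raise ValueError(f"unknown fixed-effect term {name!r}")

    names = ["intercept"]
    cols = [np.ones(len(df))]
    for name in spec.fixed:
        if name == "covariates":
            for c in data.covariate_cols:
                names.append(c)
                cols.append(df[c].to_numpy(dtype=float))
        else:
            if name in ("snp", "snp_x_age", "snp_x_time", "snp_x_age2") and g_rec is None:
                raise ValueError(f"term {name!r} requires a dosage column")
            names.append(name)
            cols.append(term(name))
    X = np.column_stack(cols)
    y = df["value"].to_numpy(dtype=float)

    slope_var = x_age if spec.random_slope == "age" else x_time
    zcols = [np.ones(len(df))]
    if spec.random_structure != "RI_only":
        zcols.append(slope_var)
    for extra in spec.extra_random_terms:
        zcols.append(term(extra))
    Z = np.column_stack(zcols)
    if with_names:
        return y, X, Z, codes, names
    return y, X, Z, codes, names


def _group_crossprods(codes, n_groups, Z, X, y):
    q, p = Z.shape[1], X.shape[1]
    ZtZ = np.empty((n_groups, q, q))
    ZtX = np.empty((n_groups, q, p))
    Zty = np.empty((n_groups, q))
    for a in range(q):
        Zty[:, a] = np.bincount(codes, Z[:, a] * y, minlength=n_groups)
        for b in range(a, q):
            v = np.bincount(codes, Z[:, a] * Z[:, b], minlength=n_groups)
            ZtZ[:, a, b] = v
            ZtZ[:, b, a] = v
        for j in range(p):
            ZtX[:, a, j] = np.bincount(codes, Z[:, a] * X[:, j], minlength=n_groups)
    return ZtZ, ZtX, Zty, X.T @ X, X.T @ y, float(y @ y)


# ---------------------------------------------------------------------------
# profiled (restricted) likelihood in Theta
# ---------------------------------------------------------------------------

def _theta_from_params(params, q, structure):
    """Log-Cholesky (correlated) or log-diagonal (uncorrelated/RI-only)."""
    L = np.zeros((q, q))
    if structure == "RI_RS_correlated" and q >= 2:
        k = 0
        for j in range(q):
            for i in range(j, q):
                L[i, j] = np.exp(params[k]) if i == j else params[k]
                k += 1
    else:
        for j in range(q):
            L[j, j] = np.exp(params[j])
    return L @ L.T


def _n_params(q, structure):
    return q * (q + 1) // 2 if structure == "RI_RS_correlated" and q >= 2 else q


class _ProfiledREML:
    def __init__(self, codes, n_groups, Z, X, y, method):
        (self.ZtZ, self.ZtX, self.Zty,
         self.XtX, self.Xty, self.yty) = _group_crossprods(codes, n_groups, Z, X, y)
        self.N, self.p = X.shape
        self.q = Z.shape[1]
        self.method = method

    def _A_logdet(self, theta):
        """A_i = Theta (I + Z_i'Z_i Theta)^-1 and sum of log det(I + Z'Z Theta)."""
        if self.q == 2:
            # hand-rolled 2x2 path: the optimizer evaluates this in a tight loop
            t00, t01, t11 = theta[0, 0], theta[0, 1], theta[1, 1]
            z00 = self.ZtZ[:, 0, 0]
            z01 = self.ZtZ[:, 0, 1]
            z11 = self.ZtZ[:, 1, 1]
            m00 = 1.0 + z00 * t00 + z01 * t01
            m01 = z00 * t01 + z01 * t11
            m10 = z01 * t00 + z11 * t01
            m11 = 1.0 + z01 * t01 + z11 * t11
            det = m00 * m11 - m01 * m10
            if np.any(det <= 0):
                return None, None
            inv00, inv01 = m11 / det, -m01 / det
            inv10, inv11 = -m10 / det, m00 / det
            A = np.empty_like(self.ZtZ)
            A[:, 0, 0] = t00 * inv00 + t01 * inv10
            A[:, 0, 1] = t00 * inv01 + t01 * inv11
            A[:, 1, 0] = t01 * inv00 + t11 * inv10
            A[:, 1, 1] = t01 * inv01 + t11 * inv11
            A = 0.5 * (A + np.swapaxes(A, 1, 2))
            return A, float(np.log(det).sum())
        M = np.eye(self.q) + self.ZtZ @ theta
        sign, logdet = np.linalg.slogdet(M)
        if np.any(sign <= 0):
            return None, None
        A = theta @ np.linalg.inv(M)
        A = 0.5 * (A + np.swapaxes(A, 1, 2))
        return A, float(logdet.sum())

    def components(self, theta):
        A, logdet_sum = self._A_logdet(theta)
        if A is None:
            return None
        AZtX = np.matmul(A, self.ZtX)                  # (n,q,p) stacked matmul
        XtWX = self.XtX - np.einsum("naq,nap->qp", self.ZtX, AZtX)
        Au = np.einsum("nab,nb->na", A, self.Zty)
        XtWy = self.Xty - np.einsum("nap,na->p", self.ZtX, Au)
        ytWy = self.yty - float(np.einsum("na,na->", self.Zty, Au))
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return None
        r2 = ytWy - XtWy @ beta
        if not np.isfinite(r2) or r2 <= 0:
            return None
        return A, XtWX, XtWy, beta, r2, logdet_sum

    def objective(self, params, structure):
        theta = _theta_from_params(params, self.q, structure)
        comp = self.components(theta)
        if comp is None:
            return 1e12
        _, XtWX, _, _, r2, logdetW = comp
        if self.method == "REML":
            sgn, ld = np.linalg.slogdet(XtWX)
            if sgn <= 0:
                return 1e12
            return logdetW + (self.N - self.p) * np.log(r2) + ld
        return logdetW + self.N * np.log(r2)

    def loglik_at(self, theta):
        """Full (restricted) log-likelihood at plug-in sigma2."""
        comp = self.components(theta)
        if comp is None:
            return -np.inf, None
        A, XtWX, XtWy, beta, r2, logdetW = comp
        if self.method == "REML":
            dof = self.N - self.p
            sigma2 = r2 / dof
            _, ld = np.linalg.slogdet(XtWX)
            ll = -0.5 * (dof * np.log(2 * np.pi * sigma2) + logdetW + ld + dof)
        else:
            sigma2 = r2 / self.N
            ll = -0.5 * (self.N * np.log(2 * np.pi * sigma2) + logdetW + self.N)
        return ll, (A, XtWX, beta, sigma2)


def fit_lmm(spec: LmmSpec, data: TrajectoryDataset,
            dosage_per_person=None, maxiter: int = 500,
            tol: float = 1e-8) -> LmmFit:
    """Fit a linear mixed model by profiled REML (or ML).

    ``dosage_per_person`` supplies the SNP column (aligned to
    ``data.person_ids``) when the spec includes SNP terms.  Non-convergence
    is returned as a flagged fit, not raised.
    """
    if data.n_persons < 2:
        raise ValueError("need at least 2 persons")
    y, X, Z, codes, names = _design_arrays(spec, data, dosage_per_person)
    n_groups = int(codes.max()) + 1
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")

    prob = _ProfiledREML(codes, n_groups, Z, X, y, spec.method)
    k = _n_params(prob.q, spec.random_structure)
    x0 = np.zeros(k)
    trace: list[float] = []

    def obj(par):
        return prob.objective(par, spec.random_structure)

    def cb(par):
        trace.append(float(obj(par)))

    res = optimize.minimize(obj, x0, method="L-BFGS-B", callback=cb, options={
        "maxiter": maxiter, "ftol": tol, "gtol": 1e-7})
    if not res.success:
        res2 = optimize.minimize(obj, res.x, method="Nelder-Mead",
                                 options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-10})
        if res2.fun <= res.fun:
            res = res2
    converged = bool(np.isfinite(res.fun) and res.fun < 1e11)

    theta = _theta_from_params(res.x, prob.q, spec.random_structure)
    ll, parts = prob.loglik_at(theta)
    if parts is None:
        raise RuntimeError("likelihood evaluation failed at optimum")
    A, XtWX, beta_int, sigma2 = parts
    cov_int = sigma2 * np.linalg.inv(XtWX)
    cov_int = 0.5 * (cov_int + cov_int.T)

    D = sigma2 * theta
    sd_i = float(np.sqrt(max(D[0, 0], 0.0)))
    sd_s = corr = None
    boundary = False
    if spec.random_structure != "RI_only":
        sd_s_int = float(np.sqrt(max(D[1, 1], 0.0)))
        sd_s = sd_s_int / spec.scale            # per year
        if spec.random_structure == "RI_RS_correlated" and sd_i > 0 and sd_s_int > 0:
            corr = float(np.clip(D[0, 1] / (sd_i * sd_s_int), -1.0, 1.0))
        else:
            corr = 0.0 if spec.random_structure == "RI_RS_uncorrelated" else None
        boundary = sd_s_int < 1e-6 * max(sd_i, 1.0) or (corr is not None and abs(corr) > 0.9999)
    boundary = boundary or sd_i < 1e-8

    scale_vec = _per_year_scaling(names, spec)
    beta = beta_int * scale_vec
    cov = cov_int * np.outer(scale_vec, scale_vec)

    fit = LmmFit(spec=spec, fixed_names=names, beta=beta, se=np.sqrt(np.diag(cov)),
                 cov_beta=cov, beta_internal=beta_int, cov_beta_internal=cov_int,
                 sd_intercept=sd_i, sd_slope=sd_s, corr=corr,
                 sigma2_residual=float(sigma2), loglik=float(ll),
                 converged=converged, boundary=boundary,
                 n_iter=int(getattr(res, "nit", -1)),
                 n_persons=n_groups, n_records=len(y), theta_internal=theta)
    fit._cache.update({"A": A, "XtWX": XtWX, "prob": prob, "dosage": dosage_per_person,
                       "objective_trace": trace})
    return fit


def _per_year_scaling(names, spec):
    """Multipliers converting internal-axis coefficients to per-year units."""
    s = np.ones(len(names))
    for i, nm in enumerate(names):
        if nm in ("age", "time", "age_baseline", "snp_x_age", "snp_x_time"):
            s[i] = 1.0 / spec.scale
        elif nm in ("age2", "snp_x_age2"):
            s[i] = 1.0 / spec.scale ** 2
        elif nm.startswith("hinge") or nm.startswith("snp_x_hinge"):
            s[i] = 1.0 / spec.scale
    return s


# ---------------------------------------------------------------------------
# BLUPs and Wald tests
# ---------------------------------------------------------------------------

def _blups_internal(fit: LmmFit, n_groups, Z, X, y, codes):
    """gamma_hat_i = Theta (I + Z_i'Z_i Theta)^-1 Z_i'(y_i - X_i beta), per person."""
    prob = fit._cache.get("prob")
    if prob is None or prob.ZtZ.shape[0] != n_groups:
        prob = _ProfiledREML(codes, n_groups, Z, X, y, fit.spec.method)
    resid_t = prob.Zty - np.einsum("naj,j->na", prob.ZtX, fit.beta_internal)
    M = np.eye(prob.q) + prob.ZtZ @ fit.theta_internal
    A = fit.theta_internal @ np.linalg.inv(M)
    A = 0.5 * (A + np.swapaxes(A, 1, 2))
    return np.einsum("nab,nb->na", A, resid_t)


def blup_random_slopes(fit: LmmFit, data: TrajectoryDataset,
                       dosage_per_person=None) -> pd.Series:
    """Per-person BLUP slope deviations gamma_hat_1i, in per-year units.

    Singletons receive defined, strongly shrunken predictions (information
    flows through the intercept-slope correlation only).
    """
    if fit.spec.random_structure == "RI_only":
        raise ValueError("model has no random slope")
    dos = dosage_per_person if dosage_per_person is not None else fit._cache.get("dosage")
    y, X, Z, codes, _ = _design_arrays(fit.spec, data, dos)
    n_groups = int(codes.max()) + 1
    gam = _blups_internal(fit, n_groups, Z, X, y, codes)
    ids = data.table.loc[~data.table["person_id"].duplicated(), "person_id"]
    return pd.Series(gam[:, 1] / fit.spec.scale, index=ids.to_numpy(), name="blup_slope")


def wald_test(fit: LmmFit, coefficient: str):
    """Two-sided normal-reference Wald test of a fixed effect.

    Returns (estimate, SE, p) on the per-year, per-allele scale.
    """
    est, se = fit.coef(coefficient)
    if se <= 0 or not np.isfinite(se):
        return est, se, np.nan
    p = 2.0 * stats.norm.sf(abs(est) / se)
    return est, se, float(p)
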