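"""Data model and I/O for longitudinal trait trajectories and genotypes.

The central container is :class:`TrajectoryDataset`, a long-format table of
repeated trait assessments (one row per person-visit) with ages, sex and
optional person-level covariates.  :class:`GenotypeMatrix` holds per-person
allele dosages in [0, 2] together with variant metadata.  The module also
implements the race-free CKD-EPI 2021 creatinine equation, the record
exclusion cascade used to clean electronic-health-record derived eGFR
trajectories, and analysis-set selection (with/without "singletons",
individuals contributing a single assessment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryDataset",
    "GenotypeMatrix",
    "QcAudit",
    "read_trajectories",
    "read_dosage_matrix",
    "read_vcf_dosages",
    "compute_egfr_ckdepi2021",
    "apply_exclusion_cascade",
    "select_analysis_set",
    "write_summary_stats",
    "read_summary_stats",
]

REQUIRED_COLUMNS = ("person_id", "age", "value")

SUMMARY_STAT_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf",
    "n_persons", "m_records", "beta_decline", "se_decline", "p_decline",
    "beta_main", "se_main", "p_main", "converged", "approach",
]


@dataclass
class TrajectoryDataset:
    """Long-format repeated trait measurements.

    Parameters
    ----------
    table
        One row per assessment with columns ``person_id``, ``age`` (years),
        ``value`` (trait units; mL/min/1.73 m^2 for eGFR), optionally ``sex``
        (0/1), ``date`` (datetime64) and any covariate columns.
    covariate_cols
        Names of person-level numeric covariate columns (e.g. genetic PCs,
        study-membership indicators).  Constant within person.
    """

    table: pd.DataFrame
    covariate_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.table
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"required column {col!r} missing")
        for col in ("age", "value"):
            if not np.issubdtype(df[col].dtype, np.number):
                raise ValueError(f"column {col!r} must be numeric")
        if not np.all(np.isfinite(df["age"])) or not np.all(np.isfinite(df["value"])):
            bad = df.index[~(np.isfinite(df["age"]) & np.isfinite(df["value"]))]
            raise ValueError(f"non-finite age/value at rows {list(bad[:5])}")
        missing = [c for c in self.covariate_cols if c not in df.columns]
        if missing:
            raise ValueError(f"covariate columns not in table: {missing}")
        df = df.sort_values(["person_id", "age"], kind="stable").reset_index(drop=True)
        df["time"] = df["age"] - df.groupby("person_id")["age"].transform("first")
        self.table = df

    # -- basic accessors -------------------------------------------------
    @property
    def person_ids(self) -> np.ndarray:
        """Unique person identifiers in table order."""
        return self.table["person_id"].unique()

    @property
    def n_persons(self) -> int:
        return self.table["person_id"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.table)

    def n_assessments(self) -> pd.Series:
        """Number of assessments per person (indexed by person_id)."""
        return self.table.groupby("person_id").size()

    def baseline(self) -> pd.DataFrame:
        """First retained assessment per person."""
        return self.table.groupby("person_id", as_index=False).first()

    def subset_persons(self, keep_ids) -> "TrajectoryDataset":
        mask = self.table["person_id"].isin(np.asarray(keep_ids))
        return TrajectoryDataset(self.table.loc[mask].copy(), list(self.covariate_cols))

    def has_sex(self) -> bool:
        return "sex" in self.table.columns


@dataclass
class GenotypeMatrix:
    """Per-person allele dosages with variant metadata.

    ``dosages`` has shape (n_variants, n_persons) aligned to ``person_ids``;
    values lie in [0, 2] and are constant across a person's repeated records
    by construction (one entry per person).
    """

    variants: pd.DataFrame  # variant_id, chrom, pos, effect_allele, other_allele, eaf
    dosages: np.ndarray
    person_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.atleast_2d(np.asarray(self.dosages, dtype=float))
        self.person_ids = np.asarray(self.person_ids)
        if self.dosages.shape != (len(self.variants), len(self.person_ids)):
            raise ValueError("dosages shape inconsistent with variants/person_ids")
        if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosage_for(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return self.dosages[idx[0]]

    def aligned_to(self, person_ids) -> np.ndarray:
        """Dosage matrix reordered to the given person_id sequence."""
        pos = pd.Series(np.arange(len(self.person_ids)), index=self.person_ids)
        try:
            take = pos.loc[np.asarray(person_ids)].to_numpy()
        except KeyError as e:
            raise KeyError(f"person ids missing from genotype matrix: {e}") from None
        return self.dosages[:, take]


@dataclass
class QcAudit:
    """Per-rule removal counts from the exclusion cascade."""

    input_records: int
    input_persons: int
    persons_removed_flags: int = 0       # AKI/nephrectomy or pre-baseline dialysis/transplant/ESKD
    records_of_removed_persons: int = 0
    removed_age_date_floor: int = 0
    removed_post_dialysis: int = 0
    removed_transplant_eskd_window: int = 0
    removed_after_prior_low: int = 0
    removed_outlier: int = 0
    winsorized_low: int = 0
    winsorized_high: int = 0
    retained_records: int = 0
    retained_persons: int = 0
    rules_skipped: list[str] = field(default_factory=list)

    def removed_records_total(self) -> int:
        return (self.removed_age_date_floor + self.removed_post_dialysis
                + self.removed_transplant_eskd_window + self.removed_after_prior_low
                + self.removed_outlier + self.records_of_removed_persons)

    def check_conservation(self) -> bool:
        return self.input_records == self.retained_records + self.removed_records_total()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trajectories(path, schema: Mapping[str, str] | None = None, sep: str | None = None,
                      covariate_cols: Sequence[str] = (),
                      on_duplicate: str = "keep") -> TrajectoryDataset:
    """Read a long-format phenotype table from a delimited text file.

    Parameters
    ----------
    schema
        Mapping from canonical names (``person_id``, ``age``, ``value``,
        ``sex``, ``date``) to column names in the file.  Identity if omitted.
    on_duplicate
        ``"keep"`` retains duplicate (person, age) rows, ``"error"`` raises.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    for col in ("age", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric {col!r} at file row(s) {[int(i) + 2 for i in bad[:5]]} "
                f"(value {df.loc[bad[0], col]!r})")
        if coerced.isna().any():
            bad = df.index[coerced.isna()]
            raise ValueError(f"missing {col!r} at file row(s) {[int(i) + 2 for i in bad[:5]]}")
        df[col] = coerced
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    dup = df.duplicated(subset=["person_id", "age"])
    if dup.any() and on_duplicate == "error":
        raise ValueError(f"duplicate (person, age) rows: {df.loc[dup, 'person_id'].tolist()[:5]}")
    return TrajectoryDataset(df, covariate_cols=list(covariate_cols))


def write_trajectories(data: TrajectoryDataset, path, sep: str = "\t") -> None:
    cols = [c for c in data.table.columns if c != "time"]
    data.table[cols].to_csv(path, sep=sep, index=False)


def read_dosage_matrix(path, sep: str = "\t") -> GenotypeMatrix:
    """Read a delimited dosage matrix: metadata columns then one column per person.

    Expected leading columns: variant_id, chrom, pos, effect_allele,
    other_allele (eaf optional; recomputed from dosages when absent).
    """
    df = pd.read_csv(path, sep=sep)
    meta_cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    for col in meta_cols:
        if col not in df.columns:
            raise ValueError(f"dosage matrix missing column {col!r}")
    has_eaf = "eaf" in df.columns
    person_cols = [c for c in df.columns if c not in meta_cols + ["eaf"]]
    dosages = df[person_cols].to_numpy(dtype=float)
    variants = df[meta_cols].copy()
    variants["eaf"] = df["eaf"] if has_eaf else dosages.mean(axis=1) / 2.0
    return GenotypeMatrix(variants.reset_index(drop=True), dosages, np.array(person_cols))


def write_dosage_matrix(gm: GenotypeMatrix, path, sep: str = "\t") -> None:
    dose = pd.DataFrame(gm.dosages, columns=[str(p) for p in gm.person_ids],
                        index=gm.variants.index)
    pd.concat([gm.variants, dose], axis=1).to_csv(path, sep=sep, index=False)


def read_vcf_dosages(path, region: str | None = None) -> GenotypeMatrix:
    """Read allele dosages from a VCF with a ``DS`` FORMAT field.

    Falls back to counting alternate alleles from hard genotypes when DS is
    absent.  The ALT allele is taken as the effect allele.
    """
    from cyvcf2 import VCF  # lazy: only needed for VCF input

    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    rows, meta = [], []
    it = vcf(region) if region else vcf
    for v in it:
        try:
            ds = np.asarray(v.format("DS"), dtype=float).reshape(-1)
        except Exception:
            gts = np.asarray(v.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
            ds = np.where(gts == 3, 2.0, np.where(gts == 2, np.nan, gts))
        rows.append(ds)
        meta.append((v.ID or f"{v.CHROM}:{v.POS}", v.CHROM, v.POS, v.ALT[0], v.REF))
    variants = pd.DataFrame(meta, columns=["variant_id", "chrom", "pos",
                                           "effect_allele", "other_allele"])
    dosages = np.vstack(rows) if rows else np.empty((0, len(samples)))
    variants["eaf"] = np.nanmean(dosages, axis=1) / 2.0 if len(rows) else []
    return GenotypeMatrix(variants, dosages, samples)


def write_summary_stats(results, path, sep: str = "\t") -> None:
    """Write association results to a GWAS-style tab-delimited table.

    ``results`` is an iterable of :class:`~longgwas.approaches.AssociationResult`
    (or anything exposing the same attribute names).  Non-converged fits are
    emitted with empty p-values and the convergence flag cleared.  Floats are
    written with 12 significant digits so the file round-trips numerically.
    """
    rows = []
    for r in results:
        rows.append({c: getattr(r, c, None) for c in SUMMARY_STAT_COLUMNS})
    df = pd.DataFrame(rows, columns=SUMMARY_STAT_COLUMNS)
    notconv = ~df["converged"].astype(bool)
    df.loc[notconv, ["p_decline", "p_main"]] = np.nan
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_summary_stats(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# eGFR
# ---------------------------------------------------------------------------

def compute_egfr_ckdepi2021(serum_creatinine, age, sex):
    """Race-free CKD-EPI 2021 creatinine equation.

    eGFR = 142 * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^-1.200
           * 0.9938^age * (1.012 if female)

    with kappa = 0.7 (female) / 0.9 (male) and alpha = -0.241 / -0.302.

    Parameters
    ----------
    serum_creatinine
        Serum creatinine in mg/dL, > 0.
    age
        Age in years, > 0.
    sex
        1/"female"/"F" for female, 0/"male"/"M" for male (scalar or array).

    Returns
    -------
    eGFR in mL/min/1.73 m^2.
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    female = _as_female_indicator(sex)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.241, -0.302)
    ratio = scr / kappa
    egfr = (142.0
            * np.minimum(ratio, 1.0) ** alpha
            * np.maximum(ratio, 1.0) ** -1.200
            * 0.9938 ** age
            * np.where(female, 1.012, 1.0))
    return egfr if egfr.ndim else float(egfr)


def _as_female_indicator(sex) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "UOS":
        return np.char.lower(arr.astype(str)).astype("U1") == "f"
    return arr.astype(bool)


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeConfig:
    min_age: float = 35.0
    date_floor: pd.Timestamp | None = pd.Timestamp("1990-01-01")
    transplant_window_days: float = 182.625  # records < 6 months before event also dropped
    low_egfr_threshold: float = 15.0
    outlier_sd_multiple: float = 10.0
    winsor_bounds: tuple[float, float] = (15.0, 200.0)

    def __post_init__(self):
        if self.outlier_sd_multiple <= 0:
            raise ValueError("outlier SD multiple must be positive")


def apply_exclusion_cascade(data: TrajectoryDataset,
                            events: pd.DataFrame | None = None,
                            config: CascadeConfig | None = None,
                            ) -> tuple[TrajectoryDataset, QcAudit]:
    """Apply the record-exclusion cascade for eGFR trajectories, in order.

    1.  Drop persons with an AKI or nephrectomy flag, or with dialysis,
        transplant or ESKD dated before their first assessment.
    2.  Drop records before age ``min_age`` (35 y) or before the date floor.
    3.  Drop records at/after dialysis onset.
    4.  Drop records < 6 months before, at or after transplant or ESKD.
    5.  Drop records after a prior value < 15.
    6.  Drop records with |conditional residual| > 10 residual SDs under the
        SNP-free age model with random intercepts and slopes fitted to the
        post-step-5 data (singletons included).
    7.  Winsorize remaining values to [15, 200].

    ``events`` is a table with columns ``person_id``, ``event``
    (aki/nephrectomy/dialysis/transplant/eskd) and ``date`` (datetime; may be
    NaT for flag-type events).  Date-based rules are skipped (and audited as
    skipped) when the trajectory table has no ``date`` column or events are
    not supplied.
    """
    cfg = config or CascadeConfig()
    df = data.table.copy()
    audit = QcAudit(input_records=len(df), input_persons=df["person_id"].nunique())
    has_dates = "date" in df.columns

    ev = None
    if events is not None and len(events):
        ev = events.copy()
        ev["event"] = ev["event"].str.lower()
        unknown = set(ev["person_id"]) - set(df["person_id"])
        if unknown:
            raise ValueError(f"events reference unknown persons: {sorted(unknown)[:5]}")

    # 1. person-level exclusions
    if ev is not None:
        flagged = set(ev.loc[ev["event"].isin(["aki", "nephrectomy"]), "person_id"])
        if has_dates:
            first_date = df.groupby("person_id")["date"].min()
            pre = ev[ev["event"].isin(["dialysis", "transplant", "eskd"]) & ev["date"].notna()]
            for pid, d in zip(pre["person_id"], pre["date"]):
                if pid in first_date.index and d < first_date.loc[pid]:
                    flagged.add(pid)
        audit.persons_removed_flags = len(flagged)
        removed_mask = df["person_id"].isin(flagged)
        audit.records_of_removed_persons = int(removed_mask.sum())
        df = df.loc[~removed_mask]
    else:
        audit.rules_skipped.append("person_flags")

    # 2. age / date floor
    drop = df["age"] < cfg.min_age
    if has_dates and cfg.date_floor is not None:
        drop |= df["date"] < cfg.date_floor
    elif cfg.date_floor is not None:
        audit.rules_skipped.append("date_floor")
    audit.removed_age_date_floor = int(drop.sum())
    df = df.loc[~drop]

    # 3./4. event windows
    if ev is not None and has_dates:
        drop = pd.Series(False, index=df.index)
        dial = ev[(ev["event"] == "dialysis") & ev["date"].notna()]
        for pid, d in zip(dial["person_id"], dial["date"]):
            drop |= (df["person_id"] == pid) & (df["date"] >= d)
        audit.removed_post_dialysis = int(drop.sum())
        df = df.loc[~drop]
        drop = pd.Series(False, index=df.index)
        tx = ev[ev["event"].isin(["transplant", "eskd"]) & ev["date"].notna()]
        window = pd.Timedelta(days=cfg.transplant_window_days)
        for pid, d in zip(tx["person_id"], tx["date"]):
            drop |= (df["person_id"] == pid) & (df["date"] >= d - window)
        audit.removed_transplant_eskd_window = int(drop.sum())
        df = df.loc[~drop]
    else:
        audit.rules_skipped.extend(["post_dialysis", "transplant_eskd_window"])

    # 5. records after a prior low value
    low_before = (df["value"] < cfg.low_egfr_threshold).groupby(df["person_id"]).cummax()
    prior_low = low_before.groupby(df["person_id"]).shift(1, fill_value=False)
    audit.removed_after_prior_low = int(prior_low.sum())
    df = df.loc[~prior_low]

    # 6. outlier screen on conditional residuals of the SNP-free age model
    if len(df) and df["person_id"].nunique() >= 2:
        resid, sigma_e = _null_model_residuals(df, list(data.covariate_cols))
        out = np.abs(resid) > cfg.outlier_sd_multiple * sigma_e
        audit.removed_outlier = int(out.sum())
        df = df.loc[~out]

    # 7. winsorize
    lo, hi = cfg.winsor_bounds
    audit.winsorized_low = int((df["value"] < lo).sum())
    audit.winsorized_high = int((df["value"] > hi).sum())
    df = df.copy()
    df["value"] = df["value"].clip(lo, hi)

    audit.retained_records = len(df)
    audit.retained_persons = df["person_id"].nunique()
    cleaned = TrajectoryDataset(df.reset_index(drop=True), list(data.covariate_cols))
    return cleaned, audit


def _null_model_residuals(df: pd.DataFrame, covariate_cols: list[str]):
    """Conditional residuals and residual SD from the SNP-free age model RI&RS."""
    from .lmm import LmmSpec, fit_lmm  # local import to avoid a cycle

    ds = TrajectoryDataset(df.copy(), covariate_cols)
    spec = LmmSpec(fixed=["sex", "age"] if "sex" in df.columns else ["age"],
                   random_structure="RI_RS_correlated", random_slope="age")
    fit = fit_lmm(spec, ds)
    resid = fit.conditional_residuals(ds)
    return resid, np.sqrt(fit.sigma2_residual)


def select_analysis_set(data: TrajectoryDataset, min_assessments: int = 2,
                        min_span: float = 1.0) -> TrajectoryDataset:
    """Select persons by assessment count and first-to-last age span.

    ``(2, 1.0)`` keeps persons with >= 2 assessments spanning >= 1 year
    ("150K-style"); ``(1, 0)`` keeps everyone including singletons
    ("350K-style").
    """
    if min_assessments < 1:
        raise ValueError("min_assessments must be >= 1")
    g = data.table.groupby("person_id")["age"]
    n = g.size()
    span = g.max() - g.min()
    keep = n.index[(n >= min_assessments) & (span >= min_span)]
    return data.subset_persons(keep)
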