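"""Simulation benchmark of the association approaches.

Repeatedly simulates genotype + trajectory data under a scenario, runs a set
of approaches on every replicate, and summarises empirical type-I error
(fraction of nominal rejections when the true decline effect is zero), power
(same fraction under a non-zero effect), relative bias of the decline-effect
estimate, and convergence rates — with exact (Clopper-Pearson) binomial
confidence intervals on the rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .approaches import APPROACHES, run_approach
from .simulate import ScenarioConfig, simulate_dataset

__all__ = ["EvaluationSummary", "estimate_rate_ci", "estimate_bias",
           "count_detected", "benchmark_approaches", "render_summary"]

BONFERRONI_595 = 0.05 / 595


@dataclass
class EvaluationSummary:
    scenario: str
    beta_decline_true: float
    reps: int
    table: pd.DataFrame          # one row per approach
    per_rep: pd.DataFrame | None = None


def estimate_rate_ci(k: int, n: int, level: float = 0.95):
    """Rate in % with exact (Clopper-Pearson) confidence interval."""
    if n == 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return 100.0 * k / n, 100.0 * ci.low, 100.0 * ci.high


def estimate_bias(estimates, beta_true: float) -> float:
    """Mean relative bias in %: 100 * mean((estimate - true) / true)."""
    if beta_true == 0:
        raise ValueError("relative bias undefined for beta_true = 0")
    est = np.asarray(estimates, dtype=float)
    est = est[np.isfinite(est)]
    return float(100.0 * np.mean((est - beta_true) / beta_true))


def count_detected(p_values, n_variants: int,
                   genomewide: float = 5e-8) -> tuple[int, int]:
    """Counts below the Bonferroni (0.05/V) and genome-wide thresholds."""
    if n_variants <= 0:
        raise ValueError("number of variants must be positive")
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    return int((p < 0.05 / n_variants).sum()), int((p < genomewide).sum())


def benchmark_approaches(scenario: ScenarioConfig, approaches=None,
                         reps: int = 500, beta_decline: float | None = None,
                         seed: int = 0, alpha: float = 0.05,
                         keep_per_rep: bool = False) -> EvaluationSummary:
    """Run every approach on ``reps`` fresh simulated datasets.

    Each replicate draws new genotypes, random effects and residuals from a
    child seed of ``seed``; the decline effect defaults to the scenario's.
    Non-converged fits are counted, never resampled.
    """
    names = list(approaches) if approaches else list(APPROACHES)
    bad = set(names) - set(APPROACHES)
    if bad:
        raise ValueError(f"unknown approach(es): {sorted(bad)}")
    if beta_decline is not None:
        scenario = dataclasses.replace(scenario, beta_decline=beta_decline)
    beta_true = scenario.beta_decline

    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(reps) % (2**31 - 1)
    records = []
    for r in range(reps):
        data, gm = simulate_dataset(scenario, seed=int(rep_seeds[r]))
        for name in names:
            res = run_approach(name, data, gm.dosages[0], gm.person_ids)
            records.append({"rep": r, "approach": name,
                            "beta": res.beta_decline, "se": res.se_decline,
                            "p": res.p_decline, "converged": res.converged})
    per_rep = pd.DataFrame(records)

    rows = []
    for name in names:
        sub = per_rep[per_rep["approach"] == name]
        ok = sub["converged"] & np.isfinite(sub["p"])
        k = int((sub.loc[ok, "p"] < alpha).sum())
        n = int(ok.sum())
        rate, lo, hi = estimate_rate_ci(k, n) if n else (np.nan, np.nan, np.nan)
        row = {"approach": name, "reps": reps, "n_used": n,
               "convergence_rate": float(sub["converged"].mean())}
        if beta_true == 0:
            row.update(t1e_pct=rate, t1e_lo=lo, t1e_hi=hi,
                       power_pct=np.nan, power_lo=np.nan, power_hi=np.nan,
                       bias_pct=np.nan)
        else:
            row.update(t1e_pct=np.nan, t1e_lo=np.nan, t1e_hi=np.nan,
                       power_pct=rate, power_lo=lo, power_hi=hi,
                       bias_pct=estimate_bias(sub.loc[ok, "beta"], beta_true))
        rows.append(row)
    label = f"{scenario.visit_scheme}, n={scenario.n_persons}, " \
            f"singletons={scenario.singleton_fraction:.0%}"
    return EvaluationSummary(scenario=label, beta_decline_true=beta_true,
                             reps=reps, table=pd.DataFrame(rows),
                             per_rep=per_rep if keep_per_rep else None)


APPROACH_LABELS = {
    "difference": "Difference model",
    "time_ri_rs": "Time model RI&RS",
    "age_ri_rs": "Age model RI&RS",
    "age_ri_rs_uncorr": "Age model RI&RS uncorr.",
    "age_ri_only": "Age model RI-only",
    "blups_linreg": "BLUPs&LinReg",
    "age_ri_rs_singletons": "Age model RI&RS (incl. singletons)",
}


def render_summary(null_summary: EvaluationSummary | None,
                   effect_summary: EvaluationSummary | None) -> str:
    """Text table of T1E / power / bias per approach."""
    names = []
    for s in (null_summary, effect_summary):
        if s is not None:
            names += [a for a in s.table["approach"] if a not in names]
    lines = [f"{'Approach':36s} {'T1E % (CI)':>22s} {'Power % (CI)':>22s} {'Bias %':>8s}"]
    for name in names:
        t1e = power = "-"
        bias = "-"
        if null_summary is not None:
            r = null_summary.table.set_index("approach")
            if name in r.index and np.isfinite(r.loc[name, "t1e_pct"]):
                t1e = (f"{r.loc[name, 't1e_pct']:.1f} "
                       f"({r.loc[name, 't1e_lo']:.1f}, {r.loc[name, 't1e_hi']:.1f})")
        if effect_summary is not None:
            r = effect_summary.table.set_index("approach")
            if name in r.index and np.isfinite(r.loc[name, "power_pct"]):
                power = (f"{r.loc[name, 'power_pct']:.1f} "
                         f"({r.loc[name, 'power_lo']:.1f}, {r.loc[name, 'power_hi']:.1f})")
                bias = f"{r.loc[name, 'bias_pct']:.1f}"
        lines.append(f"{APPROACH_LABELS.get(name, name):36s} {t1e:>22s} "
                     f"{power:>22s} {bias:>8s}")
    return "\n".join(lines)
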