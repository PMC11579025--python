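import numpy as np
import pandas as pd
import pytest
from scipy import stats

import longgwas as lg
from longgwas.data import TrajectoryDataset
from longgwas.extensions import (age_effect_curve, build_pgs,
                                 classify_stable_effect, define_rapid_decline,
                                 enrichment_test, fit_breakpoint_model,
                                 fit_location_scale, fit_quadratic_terms,
                                 prepare_ckd_subset, rapid_decline_logistic)
from longgwas.extensions import test_pgs as pgs_association
from longgwas.approaches import AssociationResult
from longgwas.lmm import LmmSpec, fit_lmm


def _result(**kw):
    base = dict(variant_id="v", approach="age_ri_rs", beta_decline=-0.001,
                se_decline=0.003, p_decline=0.5, beta_main=-0.6, se_main=0.05,
                p_main=1e-10, n_persons=1000, m_records=3000)
    base.update(kw)
    return AssociationResult(**base)


class TestEnrichment:
    def test_matches_binomial_tail_oracle_exhaustively(self):
        # independent oracle: sum of pmf terms
        for n in range(1, 21):
            for k in range(n + 1):
                oracle = sum(stats.binom.pmf(j, n, 0.05) for j in range(k, n + 1))
                assert enrichment_test(k, n) == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("k,n,expected,rel", [
        (8, 12, 1.6e-8, 0.05),    # rapid-decline enrichment of decline variants
        (4, 12, 2.2e-3, 0.05),    # decline-in-CKD enrichment
        (1, 11, 0.43, 0.02),      # stable-effect variants, one nominal hit
        (0, 11, 1.0, 1e-12),      # no hits: certain under the null
    ])
    def test_reported_enrichment_values(self, k, n, expected, rel):
        assert enrichment_test(k, n, 0.05) == pytest.approx(expected, rel=rel)

    def test_invalid_p0_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(1, 10, 0.0)


class TestEffectCurve:
    def test_effect_at_50_is_beta_main(self):
        c = age_effect_curve(-0.5, -0.05, [50.0])
        assert c.effects[0] == pytest.approx(-0.5)

    def test_linear_arithmetic(self):
        c = age_effect_curve(-0.5, -0.05, [60.0])
        assert c.effects[0] == pytest.approx(-1.0)

    def test_age_dependent_variant_value(self):
        # a decline allele with tiny effect at 50 grows large by 70
        c = age_effect_curve(-0.07, -0.024, [70.0])
        assert c.effects[0] == pytest.approx(-0.55, abs=0.005)

    def test_two_point_round_trip(self):
        c = age_effect_curve(-0.3, -0.02, [45.0, 65.0])
        slope = (c.effects[1] - c.effects[0]) / 20.0
        main = c.effects[0] - (45.0 - 50.0) * slope
        assert slope == pytest.approx(-0.02, abs=1e-12)
        assert main == pytest.approx(-0.3, abs=1e-12)

    def test_non_finite_age_rejected(self):
        with pytest.raises(ValueError):
            age_effect_curve(0.0, 0.0, [np.nan])


class TestStableEffect:
    def test_prototype_stable_variant(self):
        assert classify_stable_effect(_result())

    @pytest.mark.parametrize("kw", [
        {"p_decline": 0.05},          # nominally significant decline
        {"se_decline": 0.006},        # decline too uncertain
        {"beta_decline": -0.006},     # decline effect too large
        {"beta_main": -0.4},          # main effect too small
        {"p_main": 1e-6},             # main effect not genome-wide
    ])
    def test_each_rule_excludes(self, kw):
        assert not classify_stable_effect(_result(**kw))

    def test_exclusive_with_decline_significance(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            r = _result(p_decline=float(rng.uniform(0, 1)),
                        beta_decline=float(rng.normal(0, 0.01)))
            assert not (classify_stable_effect(r) and r.p_decline < 0.05 / 595)

    def test_missing_fields_rejected(self):
        with pytest.raises(ValueError):
            classify_stable_effect(_result(p_main=np.nan))


class TestQuadraticAndBreakpoint:
    @pytest.fixture(scope="class")
    def linear_data(self):
        cfg = lg.make_scenario("ukb_like", n_persons=500, beta_decline=-0.05)
        return lg.simulate_dataset(cfg, seed=71)

    def test_linear_generator_keeps_linear_estimate(self, linear_data):
        data, gm = linear_data
        out = fit_quadratic_terms(data, gm.dosages[0], gm.person_ids,
                                  which="snp_x_age2")
        assert out["p_term"] > 0.001     # no curvature to find
        assert out["beta_decline_augmented"] == pytest.approx(
            out["beta_decline_base"], abs=3 * out["se_augmented"])

    def test_simulated_curvature_recovered_with_sign(self):
        cfg = lg.make_scenario("ukb_like", n_persons=800, singleton_fraction=0.0)
        data, gm = lg.simulate_dataset(cfg, seed=72)
        df = data.table.copy()
        codes = pd.factorize(df["person_id"])[0]
        g = gm.dosages[0][codes]
        df["value"] = df["value"] - 0.008 * g * (df["age"] - 50.0) ** 2
        bent = TrajectoryDataset(df)
        out = fit_quadratic_terms(bent, gm.dosages[0], gm.person_ids,
                                  which="snp_x_age2")
        assert out["beta_term"] < 0
        assert out["p_term"] < 0.01

    def test_unknown_term_rejected(self, linear_data):
        data, gm = linear_data
        with pytest.raises(ValueError):
            fit_quadratic_terms(data, gm.dosages[0], gm.person_ids, which="cubic")

    def test_hinge_estimate_null_when_no_break(self, linear_data):
        data, gm = linear_data
        out = fit_breakpoint_model(data, gm.dosages[0], gm.person_ids, knot=50.0)
        assert out["beta_hinge"] == pytest.approx(0.0, abs=3 * out["se_hinge"])
        assert out["slope_after"] == pytest.approx(out["slope_before"],
                                                   abs=3 * out["se_hinge"])

    def test_true_hinge_at_50_best_detected_at_50(self):
        cfg = lg.make_scenario("ukb_like", n_persons=900, singleton_fraction=0.0,
                               age_first_mean=48.0, age_first_sd=8.0)
        data, gm = lg.simulate_dataset(cfg, seed=73)
        df = data.table.copy()
        codes = pd.factorize(df["person_id"])[0]
        g = gm.dosages[0][codes]
        df["value"] = df["value"] - 0.5 * g * np.maximum(df["age"] - 50.0, 0.0)
        bent = TrajectoryDataset(df)
        ps = {k: fit_breakpoint_model(bent, gm.dosages[0], gm.person_ids,
                                      knot=k)["p_breakpoint"] for k in (40.0, 50.0, 60.0)}
        # person-specific random slopes absorb part of any hinge signal, so
        # detection is attenuated; the knot at the true break must still win
        assert ps[50.0] < 0.01
        assert ps[50.0] == min(ps.values())

    def test_knot_outside_age_range_rejected(self, linear_data):
        data, gm = linear_data
        with pytest.raises(ValueError, match="range"):
            fit_breakpoint_model(data, gm.dosages[0], gm.person_ids, knot=120.0)


class TestLocationScale:
    @pytest.fixture(scope="class")
    def flat_data(self):
        cfg = lg.make_scenario("ukb_like", n_persons=1500, sd_intercept=3.0,
                               sd_slope=0.0, corr=0.0, sd_residual=5.0)
        return lg.simulate_dataset(cfg, seed=74)

    def test_homoscedastic_generator_null_alpha(self, flat_data):
        data, gm = flat_data
        out = fit_location_scale(data, gm.dosages[0], gm.person_ids)
        assert out["alpha_snp"] == pytest.approx(0.0, abs=3 * out["se_alpha_snp"])

    def test_variance_effect_recovered(self):
        # heteroscedastic generator: sd multiplied by exp(0.1 * dosage)
        rng = np.random.default_rng(88)
        n = 4000
        g = rng.binomial(2, 0.3, size=n).astype(float)
        age = rng.uniform(40, 75, size=n)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = (104.0 - 1.0 * (age - 50.0) + 0.5 * sex
             + rng.standard_normal(n) * 5.0 * np.exp(0.1 * g))
        df = pd.DataFrame({"person_id": np.arange(n), "age": age,
                           "value": y, "sex": sex})
        scaled = TrajectoryDataset(df)
        out = fit_location_scale(scaled, g)
        assert out["alpha_snp"] == pytest.approx(0.1, abs=3 * out["se_alpha_snp"])
        assert out["p_alpha_snp"] < 1e-4

    def test_intercept_only_scale_reduces_to_ols(self, flat_data):
        data, gm = flat_data
        out = fit_location_scale(data, gm.dosages[0], gm.person_ids,
                                 scale_terms="intercept")
        df = data.table
        codes = pd.factorize(df["person_id"])[0]
        X = np.column_stack([np.ones(len(df)), df["sex"],
                             (df["age"] - 50) / 10, gm.dosages[0][codes]])
        ols = np.linalg.lstsq(X, df["value"].to_numpy(), rcond=None)[0]
        got = np.array([out["beta"][k] for k in ("intercept", "sex", "age", "snp")])
        np.testing.assert_allclose(got, ols, atol=1e-4)


class TestClinicalTraits:
    @pytest.fixture(scope="class")
    def fitted(self, dense_panel):
        data, gm = dense_panel
        fit = fit_lmm(LmmSpec(fixed=["sex", "age"]), data)
        return data, gm, fit

    def test_rapid_decline_thresholds(self, fitted):
        data, gm, fit = fitted
        labels = define_rapid_decline(data, fit)
        from longgwas.lmm import blup_random_slopes
        total = blup_random_slopes(fit, data) + fit.coef("age")[0]
        assert (labels[total < -3.0] == 1).all()
        assert (labels[(total >= -1.0) & (total <= 1.0)] == 0).all()
        between = total[(total >= -3.0) & (total < -1.0)]
        assert labels[between.index].isna().all()

    def test_rapid_decline_logistic_runs(self, fitted):
        data, gm, fit = fitted
        labels = define_rapid_decline(data, fit, case_threshold=-1.5,
                                      control_range=(-1.0, 1.0))
        out = rapid_decline_logistic(labels, data, gm.dosages[0], gm.person_ids)
        assert 0 < out["p"] <= 1
        assert out["n_cases"] > 0 and out["n_controls"] > 0

    def test_ri_only_fit_rejected(self, dense_panel):
        data, _ = dense_panel
        fit = fit_lmm(LmmSpec(fixed=["sex", "age"], random_structure="RI_only"),
                      data)
        with pytest.raises(ValueError):
            define_rapid_decline(data, fit)

    def test_ckd_subset_rules(self):
        df = pd.DataFrame({
            "person_id": ["a"] * 3 + ["b"] * 2 + ["c"] * 2,
            "age": [50.0, 52, 54, 50, 52, 50, 52],
            "value": [70.0, 55, 50, 80, 75, 55, 58]})
        subset, labels = prepare_ckd_subset(TrajectoryDataset(df))
        assert len(subset.table.query("person_id == 'a'")) == 2   # from the 55 on
        assert "b" not in subset.person_ids                        # never below 60
        assert len(subset.table.query("person_id == 'c'")) == 2   # first value low
        assert labels.loc["a"] == 1 and labels.loc["b"] == 0 and labels.loc["c"] == 1

    def test_invalid_threshold_rejected(self, dense_panel):
        with pytest.raises(ValueError):
            prepare_ckd_subset(dense_panel[0], threshold=0.0)


class TestPgs:
    def _weights(self, gm, w):
        return pd.DataFrame({
            "variant_id": gm.variants["variant_id"],
            "effect_allele": gm.variants["effect_allele"],
            "weight": w})

    def test_single_variant_score_is_weighted_dosage(self, dense_panel):
        _, gm = dense_panel
        score = build_pgs(self._weights(gm, [-0.025]), gm)
        np.testing.assert_allclose(score.to_numpy(), -0.025 * gm.dosages[0])

    def test_allele_mismatch_detected(self, dense_panel):
        _, gm = dense_panel
        w = self._weights(gm, [-0.025])
        w["effect_allele"] = "T"
        with pytest.raises(ValueError, match="allele"):
            build_pgs(w, gm)

    def test_zero_weights_degenerate(self, dense_panel):
        data, gm = dense_panel
        score = build_pgs(self._weights(gm, [0.0]), gm)
        with pytest.raises(ValueError, match="degenerate"):
            pgs_association(score, data)

    def test_multi_variant_score_aggregates_power(self):
        """A score over several decline variants beats the median single variant."""
        rng = np.random.default_rng(75)
        n, n_var = 600, 5
        dosages = rng.binomial(2, 0.3, size=(n_var, n)).astype(float)
        variants = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(n_var)], "chrom": "1",
            "pos": np.arange(n_var) + 1, "effect_allele": "A",
            "other_allele": "G", "eaf": 0.3})
        ids = np.array([f"P{i:06d}" for i in range(n)])
        gm = lg.GenotypeMatrix(variants, dosages, ids)
        cfg = lg.make_scenario("ukb_like", n_persons=n)
        base, _ = lg.simulate_dataset(cfg, seed=76)
        df = base.table.copy()
        codes = pd.factorize(df["person_id"])[0]
        per_snp = -0.04
        joint = per_snp * dosages.sum(axis=0)
        df["value"] = df["value"] + joint[codes] * (df["age"] - 50.0)
        data = TrajectoryDataset(df)
        singles = [lg.run_approach("age_ri_rs_singletons", data, dosages[i], ids)
                   for i in range(n_var)]
        score = build_pgs(self._weights(gm, [per_snp] * n_var), gm)
        pgs_res = pgs_association(score, data)
        assert pgs_res.p_decline < np.median([r.p_decline for r in singles])
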