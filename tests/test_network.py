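"""Stage equations, cascade simulation, and derived body metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

import oncopop as op
from oncopop.network import default_coefficient_set


def _profile(**overrides):
    base = {
        "tumor": "lung", "sex": "male", "origin": "East Asian",
        "ecog": 0, "age_years": 60.0,
    }
    base.update(overrides)
    return base


class TestStageMean:
    def test_height_stage_worked_example(self, coefs):
        # 179.9 - 0.16*60 - 12.81 (female) + 3.83 (European) = 161.32 cm
        eq = coefs.stage_for("height_cm")
        mu = op.stage_mean(eq, _profile(sex="female", origin="European"))
        assert mu == pytest.approx(161.32, abs=1e-12)

    def test_aag_stage_reference_levels_leave_intercept(self, coefs):
        eq = coefs.stage_for("aag_mg_dl")
        mu = op.stage_mean(eq, _profile())
        assert mu == pytest.approx(4.32)
        assert math.exp(mu) == pytest.approx(75.2, abs=0.1)

    def test_aag_stage_all_indicators_sum(self, coefs):
        # 4.32 + 0.449 (ECOG 2) + 0.634 (Sub-Saharan African) + 0.622 (ovarian)
        eq = coefs.stage_for("aag_mg_dl")
        mu = op.stage_mean(
            eq,
            _profile(tumor="ovarian", sex="female",
                     origin="Sub-Saharan African", ecog=2),
        )
        assert mu == pytest.approx(6.025, abs=1e-12)

    def test_missing_covariate_names_stage_and_column(self, coefs):
        eq = coefs.stage_for("albumin_g_dl")
        cov = _profile()
        with pytest.raises(op.EvaluationError, match="stage 4.*aag_mg_dl"):
            op.stage_mean(eq, cov)

    def test_agrees_with_independent_symbolic_evaluation(self, coefs):
        """Dual-route check: every stage against hand-written formulas."""
        rng = np.random.default_rng(8)
        n = 100
        df = pd.DataFrame({
            "age_years": rng.uniform(18, 95, n),
            "sex": rng.choice(["male", "female"], n),
            "origin": rng.choice(list(op.ORIGINS), n),
            "ecog": rng.choice([0, 1, 2], n),
            "tumor": rng.choice(list(op.TUMORS), n),
            "height_cm": rng.uniform(140, 200, n),
            "weight_kg": rng.uniform(40, 120, n),
            "aag_mg_dl": rng.uniform(50, 400, n),
            "albumin_g_dl": rng.uniform(2, 5.5, n),
            "hb_g_dl": rng.uniform(7, 17, n),
            "nl_ratio": rng.uniform(1, 8, n),
            "pl_ratio": rng.uniform(80, 500, n),
            "crp_mg_l": rng.uniform(0.1, 80, n),
        })
        f = (df.sex == "female").to_numpy(float)
        ssa = (df.origin == "Sub-Saharan African").to_numpy(float)
        eur = (df.origin == "European").to_numpy(float)
        e1 = (df.ecog == 1).to_numpy(float)
        e2 = (df.ecog == 2).to_numpy(float)
        ov = (df.tumor == "ovarian").to_numpy(float)
        phg = df.tumor.isin(["pancreatic", "hepatic", "gastric"]).to_numpy(float)
        br = (df.tumor == "breast").to_numpy(float)
        laag = np.log(df.aag_mg_dl.to_numpy())
        oracle = {
            "height_cm": 179.9 - 0.16 * df.age_years - 12.81 * f + 6.42 * ssa + 3.83 * eur,
            "weight_kg": 2.10 + 0.012 * df.height_cm * (1 - f)
            + 0.008 * df.height_cm * f + 0.562 * f + 0.262 * ssa + 0.144 * eur,
            "aag_mg_dl": 4.32 + 0.161 * e1 + 0.449 * e2 + 0.634 * ssa
            + 0.370 * eur + 0.622 * ov,
            "albumin_g_dl": 5.546 - 0.004 * df.age_years - 0.292 * laag
            - 0.128 * e1 - 0.429 * e2 + 0.276 * ssa + 0.248 * eur - 0.339 * phg,
            "hb_g_dl": 12.35 + 0.575 * df.albumin_g_dl - 0.793 * laag - 0.680 * f,
            "nl_ratio": 1.47 - 0.0073 * laag - 0.16 * df.albumin_g_dl,
            "pl_ratio": 5.52 - 0.057 * df.hb_g_dl + 0.0016 * df.aag_mg_dl
            + 0.0622 * df.nl_ratio - 0.204 * phg,
            "crp_mg_l": 1.394 + 0.002 * df.pl_ratio + 0.368 * e1 + 0.598 * e2
            - 2.22 * br,
            "ldh_u_l": 5.709 + 0.001 * df.crp_mg_l,
            "htc_pct": 5.93 + 0.04 * laag + 2.515 * df.hb_g_dl,
        }
        for eq in coefs.equations:
            got = op.stage_mean(eq, df)
            np.testing.assert_allclose(
                got, np.asarray(oracle[eq.response], float),
                rtol=0, atol=1e-12, err_msg=eq.response,
            )


class TestStageSample:
    def test_log_weight_at_zero_noise(self, coefs):
        # exp(2.10 + 0.012*173 + 0.144) = exp(4.320) ~= 75.2 kg for a male
        eq = coefs.stage_for("weight_kg")
        y = op.stage_sample(eq, _profile(origin="European", height_cm=173.0),
                            op.ResidualStage(sd=0.0), None)
        assert y == pytest.approx(math.exp(4.320), rel=1e-12)
        assert y == pytest.approx(75.2, abs=0.1)

    def test_female_height_slope_is_reduced_by_interaction(self, coefs):
        eq = coefs.stage_for("weight_kg")
        lo = op.stage_mean(eq, _profile(sex="female", height_cm=160.0))
        hi = op.stage_mean(eq, _profile(sex="female", height_cm=161.0))
        assert hi - lo == pytest.approx(0.008, abs=1e-12)

    def test_ldh_intercept_back_transform(self, coefs):
        eq = coefs.stage_for("ldh_u_l")
        y = op.stage_sample(eq, _profile(crp_mg_l=0.0), op.ResidualStage(sd=0.0), None)
        assert y == pytest.approx(math.exp(5.709), rel=1e-12)
        assert y == pytest.approx(301.57, abs=0.1)

    def test_zero_sd_is_deterministic(self, coefs):
        eq = coefs.stage_for("crp_mg_l")
        cov = _profile(pl_ratio=200.0)
        a = op.stage_sample(eq, cov, op.ResidualStage(sd=0.0), np.random.default_rng(0))
        b = op.stage_sample(eq, cov, op.ResidualStage(sd=0.0), np.random.default_rng(1))
        assert a == b

    def test_resample_policy_keeps_draws_in_bounds(self, coefs):
        eq = coefs.stage_for("hb_g_dl")
        cov = {k: np.full(2000, v) if not isinstance(v, str) else np.full(2000, v)
               for k, v in _profile(albumin_g_dl=4.0, aag_mg_dl=150.0).items()}
        stage = op.ResidualStage(sd=3.0, policy="resample", bounds=(5.0, 20.0))
        y = op.stage_sample(eq, pd.DataFrame(cov), stage, np.random.default_rng(2))
        assert y.min() >= 5.0 and y.max() <= 20.0


class TestSimulateCohort:
    def test_zero_noise_is_pure_function_of_primaries(self, noiseless_cohort,
                                                      reference_spec, coefs,
                                                      zero_residuals):
        profiles = op.sample_primaries(reference_spec, np.random.default_rng(11))
        again = op.simulate_cohort(profiles, coefs, zero_residuals, None)
        pd.testing.assert_frame_equal(noiseless_cohort, again)

    def test_log_scale_responses_strictly_positive(self, noisy_cohort):
        for col in ["weight_kg", "aag_mg_dl", "nl_ratio", "pl_ratio",
                    "crp_mg_l", "ldh_u_l"]:
            assert (noisy_cohort[col] > 0).all()

    def test_htc_recomputable_from_own_covariates(self, noiseless_cohort, coefs):
        eq = coefs.stage_for("htc_pct")
        expected = (5.93 + 0.04 * np.log(noiseless_cohort["aag_mg_dl"])
                    + 2.515 * noiseless_cohort["hb_g_dl"])
        np.testing.assert_allclose(noiseless_cohort["htc_pct"], expected, atol=1e-12)

    def test_coefficient_direction_monotonicity(self, coefs, zero_residuals):
        base = pd.DataFrame([_profile()])
        female = pd.DataFrame([_profile(sex="female")])
        ecog2 = pd.DataFrame([_profile(ecog=2)])
        breast = pd.DataFrame([_profile(sex="female", tumor="breast")])
        fbase = pd.DataFrame([_profile(sex="female")])
        sim = lambda df: op.simulate_cohort(df, coefs, zero_residuals, None)
        assert sim(base)["height_cm"][0] - sim(female)["height_cm"][0] == pytest.approx(12.81)
        d_aag = np.log(sim(ecog2)["aag_mg_dl"][0]) - np.log(sim(base)["aag_mg_dl"][0])
        assert d_aag == pytest.approx(0.449, abs=1e-9)
        d_crp = np.log(sim(breast)["crp_mg_l"][0]) - np.log(sim(fbase)["crp_mg_l"][0])
        assert d_crp == pytest.approx(-2.22, abs=1e-9)

    def test_ecog_gradient_in_mean_aag(self, noisy_cohort):
        means = noisy_cohort.groupby("ecog")["aag_mg_dl"].mean()
        assert means[2] > means[1] > means[0]

    def test_ovarian_cohort_aag_above_east_asian_cohort(self, coefs, residuals):
        res = op.run_extrapolation(["only_ovarian", "only_east_asians"], n=1200,
                                   coefs=coefs, residuals=residuals, seed=3)
        ov = np.log(res["only_ovarian"][0]["aag_mg_dl"]).mean()
        ea = np.log(res["only_east_asians"][0]["aag_mg_dl"]).mean()
        assert ov > ea

    def test_literal_log_htc_reading_available(self, zero_residuals):
        coefs_log = default_coefficient_set(htc_log_scale=True)
        table = op.simulate_cohort(pd.DataFrame([_profile()]), coefs_log,
                                   zero_residuals, None)
        assert table["htc_pct"][0] > 1e6  # exponentiated reading is unphysiologic

    def test_network_acyclicity_enforced(self, coefs):
        eqs = list(coefs.equations)
        eqs[0], eqs[4] = eqs[4], eqs[0]  # Hb before its albumin/AAG inputs
        with pytest.raises(ValidationError, match="albumin_g_dl"):
            op.CoefficientSet(equations=tuple(eqs))


class TestDerivedMetrics:
    def test_bsa_from_cohort_mean_height_weight(self):
        assert op.derive_bsa(165.0, 72.6) == pytest.approx(1.824, abs=5e-4)
        assert round(op.derive_bsa(165.0, 72.6), 1) == 1.8

    @pytest.mark.parametrize(
        "h,w,expected", [(60.0, 60.0, 1.0), (173.0, 81.0, 1.973)]
    )
    def test_bsa_examples(self, h, w, expected):
        assert op.derive_bsa(h, w) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "h,w,expected", [(100.0, 25.0, 25.0), (165.0, 72.6, 26.67), (173.0, 81.0, 27.06)]
    )
    def test_bmi_examples(self, h, w, expected):
        assert op.derive_bmi(h, w) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize("fn", [op.derive_bsa, op.derive_bmi])
    def test_nonpositive_inputs_rejected(self, fn):
        with pytest.raises(op.DomainError):
            fn(0.0, 70.0)

    def test_stored_columns_match_recomputation(self, noisy_cohort):
        np.testing.assert_array_equal(
            noisy_cohort["bsa_m2"],
            op.derive_bsa(noisy_cohort["height_cm"], noisy_cohort["weight_kg"]),
        )
        np.testing.assert_array_equal(
            noisy_cohort["bmi_kg_m2"],
            op.derive_bmi(noisy_cohort["height_cm"], noisy_cohort["weight_kg"]),
        )
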