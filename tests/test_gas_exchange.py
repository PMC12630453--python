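"""Variable-J estimation chain: calibration, cc inversion, gm, Vcmax."""

import numpy as np
import pandas as pd
import pytest

from leafarch import gas_exchange as gx
from leafarch.phantom import (
    GasExTruth,
    records_to_frame,
    reference_protocol,
    simulate_gas_exchange,
)


def _calib_truth(truth):
    return gx.CalibrationResult(
        s=truth.s, rl_yin=truth.rl, ci_star=truth.ci_star, rl_laisk=truth.rl
    )


class TestElementaryOps:
    def test_gsc_from_gsw_arithmetic(self):
        assert gx.gsc_from_gsw(0.16) == pytest.approx(0.1)
        assert gx.gsc_from_gsw(0.0) == 0.0
        with pytest.raises(ValueError):
            gx.gsc_from_gsw(-0.1)

    def test_gsc_closes_stomatal_flux_identity(self, gasex_truth):
        recs = simulate_gas_exchange(gasex_truth, reference_protocol())
        r = recs[0]
        assert gx.gsc_from_gsw(r.gsw) * (r.ca - r.ci) == pytest.approx(r.an, rel=1e-9)

    def test_electron_transport_hand_value(self):
        df = pd.DataFrame({"qin": [700.0], "fprime": [0.6], "fmprime": [1.0]})
        assert gx.electron_transport(df, s=0.5)[0] == pytest.approx(140.0)

    def test_closed_reaction_centres_give_zero_j(self):
        df = pd.DataFrame({"qin": [700.0], "fprime": [1.0], "fmprime": [1.0]})
        with pytest.raises(ValueError):
            gx.electron_transport(df, s=0.5)
        df2 = pd.DataFrame({"qin": [700.0], "fprime": [1.0 - 1e-12], "fmprime": [1.0]})
        assert gx.electron_transport(df2, s=0.5)[0] == pytest.approx(0.0, abs=1e-6)

    def test_chloroplast_co2_hand_value(self):
        cc = gx.chloroplast_co2(10.0, 100.0, 1.0, 42.5)
        assert cc == pytest.approx(42.5 * 188.0 / 56.0)

    def test_compensation_limit(self):
        # An = -RL: cc collapses to G*
        assert gx.chloroplast_co2(-1.0, 80.0, 1.0, 42.5) == pytest.approx(42.5)

    def test_invalid_denominator_returns_nan(self):
        assert np.isnan(gx.chloroplast_co2(30.0, 100.0, 1.0, 42.5))

    def test_ficks_law_point(self):
        assert gx.mesophyll_conductance_point(10.0, 300.0, 250.0) == pytest.approx(0.2)
        assert gx.mesophyll_conductance_point(0.0, 300.0, 250.0) == 0.0


class TestYinCalibration:
    def test_exact_synthetic_line(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        an = 0.45 * x - 1.0
        # construct fluorescence so that qin*(fm-f)/fm/4 = x
        qin = np.full(4, 400.0)
        ratio = 4.0 * x / qin
        df = pd.DataFrame(
            {"qin": qin, "an": an, "fmprime": 1.0, "fprime": 1.0 - ratio}
        )
        s, rl = gx.yin_calibrate(df)
        assert s == pytest.approx(0.45, rel=1e-12)
        assert rl == pytest.approx(1.0, rel=1e-12)

    def test_recovers_simulator_truth_in_low_o2_limit(self, gasex_truth, gasex_records_clean):
        s, rl = gx.yin_calibrate(gasex_records_clean[gasex_records_clean.phase == "yin"])
        assert s == pytest.approx(gasex_truth.s, rel=1e-6)
        assert rl == pytest.approx(gasex_truth.rl, rel=1e-6)

    def test_degenerate_design_rejected(self):
        df = pd.DataFrame({"qin": [100.0, 100.0], "an": [1.0, 1.0], "fmprime": 1.0, "fprime": 0.5})
        with pytest.raises(ValueError):
            gx.yin_calibrate(df)


class TestLaisk:
    def test_three_lines_through_common_point(self):
        # lines through (ci, An) = (40, -1) with different slopes
        rows = []
        for q, b in ((110.0, 0.05), (70.0, 0.03), (50.0, 0.02)):
            for ci in (10.0, 20.0, 30.0):
                rows.append({"qin": q, "ci": ci, "an": -1.0 + b * (ci - 40.0)})
        ci_star, rl, _ = gx.laisk_ci_star(pd.DataFrame(rows))
        assert ci_star == pytest.approx(40.0, rel=1e-9)
        assert rl == pytest.approx(1.0, rel=1e-9)

    def test_recovers_simulator_truth_within_one_percent(self, gasex_truth, gasex_records_clean):
        ci_star, rl, _ = gx.laisk_ci_star(
            gasex_records_clean[gasex_records_clean.phase == "laisk"]
        )
        assert ci_star == pytest.approx(gasex_truth.ci_star, rel=0.01)
        assert rl == pytest.approx(gasex_truth.rl, rel=0.05)

    def test_parallel_lines_rejected(self):
        rows = []
        for q, a in ((110.0, 1.0), (70.0, 2.0), (50.0, 3.0)):
            for ci in (10.0, 20.0, 30.0):
                rows.append({"qin": q, "ci": ci, "an": a + 0.05 * ci})
        with pytest.raises(ValueError, match="parallel"):
            gx.laisk_ci_star(pd.DataFrame(rows))


class TestEstimateGm:
    def test_exact_calibration_recovers_gm_and_gamma_star(self, gasex_truth, gasex_records_clean):
        survey = gasex_records_clean[gasex_records_clean.phase == "survey"]
        est = gx.estimate_gm(survey, _calib_truth(gasex_truth), gamma_star_mode="iterative")
        assert est.converged and est.iterations <= 50
        assert est.gm_mean == pytest.approx(gasex_truth.gm, rel=1e-6)
        assert est.gamma_star == pytest.approx(gasex_truth.gamma_star, rel=1e-6)

    def test_fixed_mode_default_gamma_star(self, gasex_records_clean, gasex_truth):
        survey = gasex_records_clean[gasex_records_clean.phase == "survey"]
        est = gx.estimate_gm(survey, _calib_truth(gasex_truth), gamma_star_mode="fixed")
        assert est.gamma_star == 42.5
        assert est.iterations == 0

    def test_fixed_at_truth_agrees_with_iterative(self, gasex_truth, gasex_records_clean):
        survey = gasex_records_clean[gasex_records_clean.phase == "survey"]
        calib = _calib_truth(gasex_truth)
        fixed = gx.estimate_gm(
            survey, calib, gamma_star_mode="fixed", gamma_star_fixed=gasex_truth.gamma_star
        )
        it = gx.estimate_gm(survey, calib, gamma_star_mode="iterative")
        assert fixed.gm_mean == pytest.approx(it.gm_mean, rel=1e-6)

    def test_fluorescence_unit_rescaling_invariance(self, gasex_truth, gasex_records_clean):
        survey = gasex_records_clean[gasex_records_clean.phase == "survey"].copy()
        est1 = gx.estimate_gm(survey, _calib_truth(gasex_truth))
        survey[["fprime", "fmprime"]] *= 7.3
        est2 = gx.estimate_gm(survey, _calib_truth(gasex_truth))
        assert est1.gm_mean == pytest.approx(est2.gm_mean, rel=1e-12)

    def test_degenerate_records_excluded_and_counted(self, gasex_truth, gasex_records_clean):
        survey = gasex_records_clean[gasex_records_clean.phase == "survey"].copy()
        bad = survey.iloc[0].copy()
        bad["an"] = 100.0  # forces J <= 4(An+RL)
        survey = pd.concat([survey, bad.to_frame().T.astype(survey.dtypes)], ignore_index=True)
        est = gx.estimate_gm(survey, _calib_truth(gasex_truth), gamma_star_mode="fixed",
                             gamma_star_fixed=gasex_truth.gamma_star)
        assert est.n_invalid == 1
        assert not est.per_record["valid"].iloc[-1]
        assert np.isnan(est.per_record["gm"].iloc[-1])


class TestVcmax:
    def test_exact_line_machine_precision(self):
        constants = gx.KineticConstants(kc=404.9, ko=278.4, o2=210.0)
        cc = np.array([150.0, 200.0, 250.0, 300.0])
        x = (cc - 42.5) / (cc + constants.km)
        an = 60.0 * x - 1.0
        df = pd.DataFrame({"an": an})
        fit = gx.fit_vcmax(df, constants, 42.5, cc=cc)
        assert fit.vcmax == pytest.approx(60.0, rel=1e-12)
        assert fit.rl_fit == pytest.approx(1.0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_simulator_rubisco_limited_recovery(self, gasex_truth, gasex_records_clean):
        survey = gasex_records_clean[gasex_records_clean.phase == "survey"]
        constants = gx.KineticConstants(kc=gasex_truth.kc, ko=gasex_truth.ko, o2=210.0)
        est = gx.estimate_gm(survey, _calib_truth(gasex_truth), gamma_star_mode="iterative")
        fit = gx.fit_vcmax(survey, constants, est.gamma_star, cc=est.per_record["cc"].to_numpy())
        assert fit.vcmax == pytest.approx(gasex_truth.vcmax, rel=1e-3)

    def test_mixed_regime_warns_and_biases_low(self, gasex_truth):
        # records spanning the RuBP-regeneration-limited regime at low light
        from leafarch.phantom import ProtocolStep

        steps = [ProtocolStep("survey", ca, 150.0, 210.0) for ca in (200, 300, 500, 800, 1200)]
        recs = records_to_frame(simulate_gas_exchange(gasex_truth, steps))
        cc_true = [r.cc_true for r in simulate_gas_exchange(gasex_truth, steps)]
        constants = gx.KineticConstants(kc=gasex_truth.kc, ko=gasex_truth.ko, o2=210.0)
        with pytest.warns(UserWarning, match="biased low"):
            fit = gx.fit_vcmax(recs, constants, gasex_truth.gamma_star, cc=np.asarray(cc_true))
        assert fit.vcmax < gasex_truth.vcmax

    def test_rank_deficiency_rejected(self):
        constants = gx.KineticConstants(kc=404.9, ko=278.4, o2=210.0)
        df = pd.DataFrame({"an": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            gx.fit_vcmax(df, constants, 42.5, cc=np.array([100.0, 100.0, 100.0]))


class TestFullChain:
    def test_zero_noise_pipeline_recovery(self, gasex_truth, gasex_records_clean):
        df = gasex_records_clean
        s, rl = gx.yin_calibrate(df[df.phase == "yin"])
        ci_star, rl_l, _ = gx.laisk_ci_star(df[df.phase == "laisk"])
        calib = gx.CalibrationResult(s=s, rl_yin=rl, ci_star=ci_star, rl_laisk=rl_l)
        est = gx.estimate_gm(df[df.phase == "survey"], calib, gamma_star_mode="iterative")
        # s and RL are exact in the low-O2 limit; the regression-intercept
        # ci* carries the intrinsic linearisation bias of the method (the
        # An-ci response is hyperbolic), which propagates to G* and gm
        assert s == pytest.approx(gasex_truth.s, rel=1e-6)
        assert rl == pytest.approx(gasex_truth.rl, rel=1e-6)
        assert ci_star == pytest.approx(gasex_truth.ci_star, rel=0.01)
        assert est.gamma_star == pytest.approx(gasex_truth.gamma_star, rel=0.01)
        assert est.gm_mean == pytest.approx(gasex_truth.gm, rel=0.02)

    def test_noisy_monte_carlo_median_gm_bias(self):
        # 2% multiplicative noise on the primary instrument channels;
        # within-dataset aggregation by median, as 1/(ci - cc) is convex
        # and mean aggregation inflates gm under noise
        import warnings

        biases = []
        for seed in range(40):
            truth = GasExTruth(
                noise_sd={"an": 0.02, "gsw": 0.02, "phi": 0.02}, rng_seed=seed
            )
            prot = reference_protocol(
                survey_ca=(410.0, 360.0, 310.0, 410.0) * 5, yin_o2=0.0
            )
            df = records_to_frame(simulate_gas_exchange(truth, prot))
            try:
                s, rl = gx.yin_calibrate(df[df.phase == "yin"])
                ci_star, _, _ = gx.laisk_ci_star(df[df.phase == "laisk"])
                calib = gx.CalibrationResult(s=s, rl_yin=rl, ci_star=ci_star)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est = gx.estimate_gm(
                        df[df.phase == "survey"], calib,
                        gamma_star_mode="iterative", aggregate="median",
                    )
            except ValueError:
                continue
            if est.converged:
                biases.append(est.gm_mean / truth.gm - 1.0)
        assert len(biases) >= 30
        assert abs(np.median(biases)) <= 0.05
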