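import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calscreen.core import CompoundRecord, R1Class, R2Class
from calscreen.pharm import (
    GEA133_TMRM_4PL,
    FourPLParams,
    Mechanism,
    SecretaseProfile,
    build_profile,
    classify_mechanism,
    fit_4pl,
    fit_calibration,
    invert_4pl,
    predict_4pl,
    quantify_samples,
    sar_summary,
)
from calscreen.synth import simulate_dose_table

P = FourPLParams(bottom=0.5, top=2.5, ec50=4e-6, hill=1.3)


class TestPredict:
    def test_midpoint_at_ec50(self):
        assert predict_4pl(P, P.ec50) == pytest.approx((P.top + P.bottom) / 2)

    def test_low_limit_bottom(self):
        assert predict_4pl(P, 1e-18) == pytest.approx(P.bottom, abs=1e-9)

    def test_high_limit_top(self):
        assert predict_4pl(P, 1e3) == pytest.approx(P.top, abs=1e-9)

    def test_hill_sign_mirrors_direction(self):
        flipped = FourPLParams(P.bottom, P.top, P.ec50, -P.hill)
        lo, hi = 1e-9, 1e-3
        assert predict_4pl(P, lo) < predict_4pl(P, hi)
        assert predict_4pl(flipped, lo) > predict_4pl(flipped, hi)
        # mirror identity around the midpoint
        assert predict_4pl(flipped, 10 * P.ec50) == pytest.approx(
            predict_4pl(P, P.ec50 / 10), rel=1e-12
        )

    def test_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            predict_4pl(P, 0.0)


class TestInvert:
    def test_midpoint_gives_ec50(self):
        assert invert_4pl(P, (P.top + P.bottom) / 2) == pytest.approx(P.ec50, rel=1e-12)

    def test_round_trip_20_random(self):
        rng = np.random.default_rng(2)
        for c in 10 ** rng.uniform(-8, -4, 20):
            assert invert_4pl(P, predict_4pl(P, c)) == pytest.approx(c, rel=1e-9)

    @pytest.mark.parametrize("sig,bound", [(2.5, "top"), (2.6, "top"), (0.5, "bottom"), (0.4, "bottom")])
    def test_out_of_range_names_bound(self, sig, bound):
        with pytest.raises(ValueError, match=bound):
            invert_4pl(P, sig)

    def test_decreasing_curve_round_trip(self):
        down = FourPLParams(bottom=0.1, top=1.0, ec50=2e-6, hill=-1.1)
        for c in (1e-7, 2e-6, 5e-5):
            assert invert_4pl(down, predict_4pl(down, c)) == pytest.approx(c, rel=1e-9)


class TestFit:
    def test_noiseless_recovery(self):
        concs = np.logspace(-8, -4, 8)
        resp = predict_4pl(P, concs)
        fit = fit_4pl(np.repeat(concs, 3), np.repeat(resp, 3))
        assert fit.converged and not fit.degenerate
        assert fit.params.ec50 == pytest.approx(P.ec50, rel=1e-6)
        assert fit.params.hill == pytest.approx(P.hill, rel=1e-6)
        assert fit.params.bottom == pytest.approx(P.bottom, abs=1e-6)
        assert fit.params.top == pytest.approx(P.top, abs=1e-6)

    def test_decreasing_curve_recovery(self):
        down = FourPLParams(bottom=0.2, top=1.0, ec50=3e-6, hill=-1.0)
        concs = np.logspace(-8, -4, 6)
        fit = fit_4pl(concs, predict_4pl(down, concs))
        assert fit.params.ec50 == pytest.approx(down.ec50, rel=1e-5)

    def test_flat_data_degenerate(self):
        concs = np.repeat(np.logspace(-8, -5, 6), 4)
        rng = np.random.default_rng(0)
        resp = 1.0 + rng.normal(0, 0.05, concs.size)  # pure noise, no trend
        fit = fit_4pl(concs, resp)
        assert fit.degenerate
        assert fit.params is None

    def test_all_equal_degenerate(self):
        concs = np.repeat(np.logspace(-8, -5, 6), 2)
        fit = fit_4pl(concs, np.ones(concs.size))
        assert fit.degenerate

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError):
            fit_4pl([1e-6, 2e-6, 4e-6], [1.0, 1.5, 2.0])

    def test_median_ec50_error_under_noise(self):
        # full-dynamic-range curve sampled across both asymptotes
        truth = FourPLParams(bottom=0.1, top=2.0, ec50=4.84e-6, hill=1.0)
        concs = np.logspace(np.log10(0.05e-6), np.log10(300e-6), 6)
        errs = []
        for seed in range(40):
            df = simulate_dose_table(truth, concs, n_replicates=8, noise_cv=0.10, seed=seed)
            fit = fit_4pl(df["concentration"], df["response"])
            errs.append(abs(fit.params.ec50 - truth.ec50) / truth.ec50)
        assert np.median(errs) < 0.10

    def test_median_bias_small(self):
        truth = FourPLParams(bottom=0.1, top=2.0, ec50=4.84e-6, hill=1.0)
        concs = np.logspace(np.log10(0.05e-6), np.log10(300e-6), 6)
        signed = []
        for seed in range(200):
            df = simulate_dose_table(truth, concs, n_replicates=8, noise_cv=0.10, seed=seed)
            fit = fit_4pl(df["concentration"], df["response"])
            signed.append((fit.params.ec50 - truth.ec50) / truth.ec50)
        assert abs(np.median(signed)) < 0.02


class TestCalibrationAndQuantify:
    CAL = FourPLParams(bottom=40.0, top=15000.0, ec50=150e-12, hill=1.05)
    STDS = np.logspace(np.log10(2e-12), np.log10(5e-9), 8)

    def _calib(self):
        return fit_calibration("abeta42", self.STDS, predict_4pl(self.CAL, self.STDS))

    def test_too_few_standards(self):
        with pytest.raises(ValueError):
            fit_calibration("abeta42", self.STDS[:5], predict_4pl(self.CAL, self.STDS[:5]))

    def test_identical_signals_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration("abeta42", self.STDS, np.ones(8))

    def test_narrow_span_warns(self):
        narrow = np.linspace(1e-10, 5e-10, 6)
        calib = fit_calibration("abeta42", narrow, predict_4pl(self.CAL, narrow))
        assert "log-units" in calib.warning

    def test_quantify_recovers_concentrations(self):
        calib = self._calib()
        true_c = [10e-12, 150e-12, 2e-9]
        df = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "signal": [predict_4pl(self.CAL, c) for c in true_c],
            }
        )
        out = quantify_samples(calib, df)
        np.testing.assert_allclose(out["concentration"], true_c, rtol=1e-3)
        assert (out["flag"] == "ok").all()

    def test_above_top_standard_flagged(self):
        calib = self._calib()
        df = pd.DataFrame({"sample_id": ["hot"], "signal": [predict_4pl(self.CAL, 1e-7)]})
        out = quantify_samples(calib, df)
        assert out["flag"].iloc[0] == "above_range"

    def test_saturated_signal_flagged(self):
        calib = self._calib()
        df = pd.DataFrame({"sample_id": ["sat"], "signal": [calib.curve.top * 1.01]})
        assert quantify_samples(calib, df)["flag"].iloc[0] == "above_range"

    def test_duplicate_replicates_same_as_single(self):
        calib = self._calib()
        s = predict_4pl(self.CAL, 100e-12)
        single = quantify_samples(calib, pd.DataFrame({"sample_id": ["x"], "signal": [s]}))
        dup = quantify_samples(
            calib, pd.DataFrame({"sample_id": ["x", "x"], "signal": [s, s]})
        )
        assert dup["concentration"].iloc[0] == pytest.approx(single["concentration"].iloc[0])


def profile(app, c99=None, sappa=None, sappb=None):
    return SecretaseProfile("x", app, c99, sappa, sappb)


ABD = {"abeta38": 0.2, "abeta40": 0.2, "abeta42": 0.2}
ONES = {"abeta38": 1.0, "abeta40": 1.0, "abeta42": 1.0}


class TestBuildProfile:
    def _tables(self, app_levels, vehicle_conc=1.0):
        rows = []
        for analyte, lvl in app_levels.items():
            rows.append({"analyte": analyte, "sample_id": "DMSO", "concentration": vehicle_conc})
            rows.append({"analyte": analyte, "sample_id": "x", "concentration": vehicle_conc * lvl})
        return {"app": pd.DataFrame(rows)}

    def test_vehicle_is_unity(self):
        prof = build_profile(self._tables(ONES), "DMSO", "DMSO")
        assert all(v == pytest.approx(1.0) for v in prof.app_levels.values())
        assert prof.ratio_42_40("app") == pytest.approx(1.0)

    def test_proportional_reduction_keeps_ratio(self):
        prof = build_profile(
            self._tables({"abeta38": 0.5, "abeta40": 0.5, "abeta42": 0.5}), "DMSO", "x"
        )
        assert prof.ratio_42_40("app") == pytest.approx(1.0)

    def test_selective_reduction_shifts_ratio(self):
        prof = build_profile(
            self._tables({"abeta38": 1.0, "abeta40": 1.0, "abeta42": 0.5}), "DMSO", "x"
        )
        assert prof.ratio_42_40("app") == pytest.approx(0.5)

    def test_vehicle_scale_cancels(self):
        p1 = build_profile(self._tables(ABD, vehicle_conc=1.0), "DMSO", "x")
        p2 = build_profile(self._tables(ABD, vehicle_conc=123.4), "DMSO", "x")
        assert p1.ratio_42_40("app") == pytest.approx(p2.ratio_42_40("app"), rel=1e-12)

    def test_missing_analyte_partial(self):
        prof = build_profile(self._tables({"abeta40": 1.0, "abeta42": 1.0}), "DMSO", "x")
        assert prof.partial

    def test_missing_vehicle_rejected(self):
        t = {"app": pd.DataFrame([{"analyte": "abeta40", "sample_id": "x", "concentration": 1.0}])}
        with pytest.raises(ValueError):
            build_profile(t, "DMSO", "x")


class TestClassifyMechanism:
    def test_gamma_inhibitor(self):
        call = classify_mechanism(profile(dict(ABD), dict(ABD)))
        assert call.mechanism is Mechanism.GAMMA_INHIBITOR

    def test_gamma_modulator(self):
        app = {"abeta38": 1.6, "abeta40": 1.0, "abeta42": 0.5}
        call = classify_mechanism(profile(app))
        assert call.mechanism is Mechanism.GAMMA_MODULATOR

    def test_inverse_gamma_modulator(self):
        c99 = {"abeta38": 0.9, "abeta40": 0.7, "abeta42": 1.1}  # ratio ~1.57
        call = classify_mechanism(profile(dict(ONES), c99))
        assert call.mechanism is Mechanism.INVERSE_GAMMA_MODULATOR

    def test_beta_cleavage_reduction_with_c99(self):
        app = {"abeta38": 0.5, "abeta40": 0.5, "abeta42": 0.5}
        call = classify_mechanism(profile(app, dict(ONES), sappa=1.0, sappb=0.5))
        assert call.mechanism is Mechanism.BETA_CLEAVAGE_REDUCTION

    def test_beta_cleavage_reduction_needs_sapp_without_c99(self):
        app = {"abeta38": 0.5, "abeta40": 0.5, "abeta42": 0.5}
        assert (
            classify_mechanism(profile(app, sappa=1.0, sappb=0.5)).mechanism
            is Mechanism.BETA_CLEAVAGE_REDUCTION
        )
        assert (
            classify_mechanism(profile(app)).mechanism is Mechanism.UNCLASSIFIED
        )

    def test_no_effect(self):
        call = classify_mechanism(profile(dict(ONES), dict(ONES), sappa=1.0, sappb=1.0))
        assert call.mechanism is Mechanism.NO_EFFECT

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            classify_mechanism(profile({}))

    def test_analyte_order_invariance(self):
        app = {"abeta42": 0.5, "abeta38": 1.6, "abeta40": 1.0}
        reordered = {"abeta38": 1.6, "abeta40": 1.0, "abeta42": 0.5}
        assert (
            classify_mechanism(profile(app)).mechanism
            == classify_mechanism(profile(reordered)).mechanism
        )

    @settings(max_examples=100, deadline=None)
    @given(
        levels=st.lists(st.floats(0.05, 3.0), min_size=3, max_size=3),
        with_c99=st.booleans(),
    )
    def test_property_total_single_class(self, levels, with_c99):
        app = dict(zip(("abeta38", "abeta40", "abeta42"), levels))
        c99 = dict(ONES) if with_c99 else None
        call = classify_mechanism(profile(app, c99))
        assert isinstance(call.mechanism, Mechanism)


class TestSarSummary:
    def test_active_combination(self):
        recs = [CompoundRecord("gea", R1Class.CYANO, R2Class.BENZYLPIPERIDINYL)]
        table = sar_summary(recs)
        assert table["expected_label"].iloc[0] == "expected-active"

    def test_inactive_combination(self):
        recs = [CompoundRecord("dud", R1Class.HYDROGEN, R2Class.ALIPHATIC)]
        assert sar_summary(recs)["expected_label"].iloc[0] == "expected-inactive"

    def test_aliphatic_overrides_ewg(self):
        recs = [CompoundRecord("m", R1Class.NITRO, R2Class.ALIPHATIC)]
        assert sar_summary(recs)["expected_label"].iloc[0] == "expected-inactive"

    def test_empty_list(self):
        assert sar_summary([]).empty

    def test_activity_means_merged(self):
        recs = [
            CompoundRecord("a", R1Class.NITRO, R2Class.BENZYLPIPERIDINYL),
            CompoundRecord("b", R1Class.NITRO, R2Class.BENZYLPIPERIDINYL),
        ]
        res = pd.DataFrame({"compound_id": ["a", "b"], "norm_mean": [0.7, 0.8]})
        table = sar_summary(recs, res)
        assert table["mean_norm_mean"].iloc[0] == pytest.approx(0.75)


class TestPreset:
    def test_gea133_preset_midpoint(self):
        assert predict_4pl(GEA133_TMRM_4PL, 4.84e-6) == pytest.approx(1.5)
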