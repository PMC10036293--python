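"""Normative regression, w-scores and percentile conversions.

The OLS fit is checked against a direct normal-equations oracle, and the
w-score invariances (zero in-sample mean, unit-change and covariate-shift
invariance, out-of-sample calibration) are exercised on generated cohorts.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ftdnorm import (NormativeFitError, UnseenScannerError, compute_wscores,
                     fit_normative_models, generate_controls,
                     percentile_cutpoint, predict_expected, wscore_percentile)

from conftest import controls_only_spec, small_roi_model


def _controls_frame(age, sex, tiv, scanner, pid=None):
    n = len(age)
    return pd.DataFrame({
        "participant_id": pid or [f"P{i}" for i in range(n)],
        "group": "control", "stage": "control",
        "age_years": age, "sex": sex, "tiv_mm3": tiv, "scanner": scanner,
        "visit": "baseline", "cdr_global": 0.0, "cdr_sb": 0.0, "cbir": 0.0})


def _measures_frame(controls, values, roi="hippocampus", modality="volume"):
    return pd.DataFrame({"participant_id": controls["participant_id"],
                         "roi": roi, "modality": modality, "value": values})


class TestFit:
    def test_coefficients_match_normal_equations_oracle(self):
        # 6-row fixture, two scanner categories -> 5 parameters
        controls = _controls_frame(
            age=[30.0, 40.0, 50.0, 60.0, 35.0, 55.0],
            sex=["male", "female", "male", "female", "female", "male"],
            tiv=[1.40e6, 1.50e6, 1.45e6, 1.38e6, 1.52e6, 1.47e6],
            scanner=["SiemensTrio", "SiemensTrio", "SiemensPrisma",
                     "SiemensTrio", "SiemensPrisma", "SiemensTrio"])
        y = np.array([7100.0, 7300.0, 6900.0, 7050.0, 7400.0, 6800.0])
        models = fit_normative_models(controls, _measures_frame(controls, y))
        m = models[("hippocampus", "volume")]
        # independent brute-force oracle: beta = (X'X)^-1 X'y
        X = np.column_stack([
            np.ones(6), controls["age_years"],
            (controls["sex"] == "male").astype(float), controls["tiv_mm3"],
            (controls["scanner"] == "SiemensPrisma").astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fitted = [m.coefficients[k] for k in
                  ("intercept", "age_years", "sex_male", "tiv_mm3",
                   "scanner_SiemensPrisma")]
        np.testing.assert_allclose(fitted, beta, rtol=0, atol=1e-8)
        assert m.reference_scanner == "SiemensTrio"
        resid = y - X @ beta
        assert m.sigma == pytest.approx(np.sqrt(resid @ resid / (6 - 5)))

    def test_constant_values_give_degenerate_model(self):
        spec = controls_only_spec(60)
        controls, _ = generate_controls(spec, small_roi_model(), seed=1)
        measures = _measures_frame(controls, np.full(60, 100.0))
        models = fit_normative_models(controls, measures)
        m = models[("hippocampus", "volume")]
        assert m.degenerate
        assert m.sigma == pytest.approx(0.0, abs=1e-9)
        assert m.coefficients["intercept"] == pytest.approx(100.0, abs=1e-6)
        for k, v in m.coefficients.items():
            if k != "intercept":
                assert v == pytest.approx(0.0, abs=1e-6)
        # degenerate models never score
        scored = compute_wscores(models, controls, measures)
        assert scored.empty

    def test_five_scanner_categories_give_four_offsets(self, fitted_models):
        m = fitted_models[("hippocampus", "volume")]
        offsets = [k for k in m.coefficients if k.startswith("scanner_")]
        assert len(offsets) == 4
        assert f"scanner_{m.reference_scanner}" not in m.coefficients

    def test_rank_deficient_design_names_collinear_column(self):
        controls = _controls_frame(
            age=[30.0, 40.0, 50.0, 60.0, 35.0, 55.0, 45.0],
            sex=["male"] * 7,  # sex_male constant -> collinear with intercept
            tiv=[1.4e6, 1.5e6, 1.45e6, 1.38e6, 1.52e6, 1.47e6, 1.41e6],
            scanner=["SiemensTrio", "SiemensPrisma"] * 3 + ["SiemensTrio"])
        measures = _measures_frame(controls, np.arange(7.0))
        with pytest.raises(NormativeFitError, match="sex_male"):
            fit_normative_models(controls, measures)

    def test_all_missing_roi_skipped_with_record(self, control_tables):
        controls, measures = control_tables
        measures = measures.copy()
        measures.loc[measures["roi"] == "hippocampus", "value"] = np.nan
        models = fit_normative_models(controls, measures)
        assert ("hippocampus", "volume") in models.skipped
        assert ("uf", "FA") in models.models

    def test_sigma_df_convention_switch(self, control_tables):
        controls, measures = control_tables
        m_np = fit_normative_models(controls, measures, sigma_df="n-p")
        m_n1 = fit_normative_models(controls, measures, sigma_df="n-1")
        key = ("hippocampus", "volume")
        n, p = 240, 8
        ratio = m_np[key].sigma / m_n1[key].sigma
        assert ratio == pytest.approx(np.sqrt((n - 1) / (n - p)))


class TestPredict:
    def test_prediction_at_covariate_means_is_value_mean(self):
        # OLS passes through the means: predicting at the average covariates
        # of the fitting sample returns the average fitted (= observed) value
        spec = controls_only_spec(100)
        controls, measures = generate_controls(spec, small_roi_model(), seed=2)
        one_scanner = controls.assign(scanner="SiemensTrio")
        models = fit_normative_models(one_scanner,
                                      measures[measures["roi"] == "hippocampus"])
        m = models[("hippocampus", "volume")]
        pred = predict_expected(
            m, age=one_scanner["age_years"].mean(),
            sex="female", tiv=one_scanner["tiv_mm3"].mean(),
            scanner="SiemensTrio")
        prop_male = (one_scanner["sex"] == "male").mean()
        pred += m.coefficients["sex_male"] * prop_male  # continuous sex mean
        assert pred == pytest.approx(measures[measures["roi"] == "hippocampus"]
                                     ["value"].mean(), rel=1e-9)

    def test_linearity_in_age(self, fitted_models):
        m = fitted_models[("hippocampus", "volume")]
        p40 = predict_expected(m, 40.0, "male", 1.45e6, "SiemensTrio")
        p50 = predict_expected(m, 50.0, "male", 1.45e6, "SiemensTrio")
        assert p50 - p40 == pytest.approx(10 * m.coefficients["age_years"], rel=1e-12)

    def test_unseen_scanner_is_an_error(self, fitted_models):
        m = fitted_models[("hippocampus", "volume")]
        with pytest.raises(UnseenScannerError, match="7T-X"):
            predict_expected(m, 40.0, "male", 1.45e6, "7T-X")


class TestWScores:
    def test_observed_equals_predicted_gives_zero(self, fitted_models, control_tables):
        controls, measures = control_tables
        m = fitted_models[("hippocampus", "volume")]
        row = controls.iloc[0]
        pred = predict_expected(m, row["age_years"], row["sex"],
                                row["tiv_mm3"], row["scanner"])
        one = pd.DataFrame({"participant_id": [row["participant_id"]],
                            "roi": "hippocampus", "modality": "volume",
                            "value": [pred]})
        scored = compute_wscores(fitted_models, controls, one)
        assert scored["wscore"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_explicit_wscore_value(self):
        # (935.9 - 1000) / 50 = -1.282
        assert (935.9 - 1000.0) / 50.0 == pytest.approx(-1.282)

    def test_in_sample_control_mean_is_zero(self, fitted_models, control_tables):
        controls, measures = control_tables
        scored = compute_wscores(fitted_models, controls, measures)
        per_roi = scored.groupby(["roi", "modality"])["wscore"].mean()
        assert per_roi.abs().max() < 1e-10

    def test_in_sample_control_sd_near_one(self, fitted_models, control_tables):
        controls, measures = control_tables
        scored = compute_wscores(fitted_models, controls, measures)
        per_roi = scored.groupby(["roi", "modality"])["wscore"].std()
        assert per_roi.between(0.95, 1.05).all()

    def test_covariate_shift_invariance(self, control_tables, carrier_tables):
        # adding a constant to every age (and TIV) leaves w-scores unchanged
        controls, cmeas = control_tables
        carriers, kmeas = carrier_tables
        base = compute_wscores(fit_normative_models(controls, cmeas),
                               carriers, kmeas)
        shifted_c = controls.assign(age_years=controls["age_years"] + 7.0,
                                    tiv_mm3=controls["tiv_mm3"] + 1e4)
        shifted_k = carriers.assign(age_years=carriers["age_years"] + 7.0,
                                    tiv_mm3=carriers["tiv_mm3"] + 1e4)
        shifted = compute_wscores(fit_normative_models(shifted_c, cmeas),
                                  shifted_k, kmeas)
        np.testing.assert_allclose(base["wscore"], shifted["wscore"], atol=1e-9)

    def test_unit_change_invariance(self, control_tables, carrier_tables):
        # multiplying one ROI's raw values by 1000 and refitting leaves w unchanged
        controls, cmeas = control_tables
        carriers, kmeas = carrier_tables
        base = compute_wscores(fit_normative_models(controls, cmeas),
                               carriers, kmeas)
        scale = np.where(cmeas["roi"] == "hippocampus", 1000.0, 1.0)
        kscale = np.where(kmeas["roi"] == "hippocampus", 1000.0, 1.0)
        rescaled = compute_wscores(
            fit_normative_models(controls, cmeas.assign(value=cmeas["value"] * scale)),
            carriers, kmeas.assign(value=kmeas["value"] * kscale))
        np.testing.assert_allclose(base["wscore"], rescaled["wscore"], atol=1e-9)

    def test_held_out_controls_are_standard_normal(self):
        # KS statistic below the 5% critical value in >= 90% of repetitions
        model = {("hippocampus", "volume"): small_roi_model()[("hippocampus", "volume")]}
        n_held = 200
        crit = 1.358 / np.sqrt(n_held)
        passes = 0
        reps = 20
        for rep in range(reps):
            train, tmeas = generate_controls(controls_only_spec(240), model,
                                             seed=1000 + rep)
            held, hmeas = generate_controls(controls_only_spec(n_held), model,
                                            seed=5000 + rep)
            models = fit_normative_models(train, tmeas)
            w = compute_wscores(models, held, hmeas)["wscore"]
            if stats.kstest(w, "norm").statistic < crit:
                passes += 1
        assert passes >= 0.9 * reps


class TestPercentiles:
    @pytest.mark.parametrize("p, w", [(0.025, -1.960), (0.05, -1.645),
                                      (0.10, -1.282), (0.25, -0.675),
                                      (0.5, 0.0)])
    def test_cutpoints_match_normal_quantiles(self, p, w):
        # quoted constants are rounded to 3 decimals (-0.6745 -> -0.675)
        assert percentile_cutpoint(p) == pytest.approx(w, abs=6e-4)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.7])
    def test_cutpoint_rejects_out_of_range(self, p):
        with pytest.raises(ValueError):
            percentile_cutpoint(p)

    def test_percentile_of_zero_is_fifty(self):
        assert wscore_percentile(0.0) == pytest.approx(50.0)

    def test_quarter_percentile(self):
        assert round(float(wscore_percentile(-0.675))) == 25

    @given(st.floats(min_value=-4.0, max_value=4.0))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_inverse(self, w):
        assert percentile_cutpoint(float(wscore_percentile(w)) / 100.0) == \
            pytest.approx(w, abs=1e-9)
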