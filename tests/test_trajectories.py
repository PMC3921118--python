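"""Growth curves: pruning, prediction bands, curve-contrast F-tests."""

import numpy as np
import pandas as pd
import pytest

from lctraj.trajectories import (
    GROUP_FREE,
    curve_contrast_test,
    fit_growth_curve,
    predict_curve,
)

from conftest import two_group_null_frame


def _labels(df):
    return df.drop_duplicates("subject_id").set_index("subject_id")["group_truth"]


@pytest.fixture(scope="module")
def bmi_growth_fit(tracked_cohort):
    _, dataset, _, labels = tracked_cohort
    return fit_growth_curve("bmi", dataset, labels)


class TestFitGrowthCurve:
    def test_diabetes_free_group_is_linear(self, bmi_growth_fit):
        assert bmi_growth_fit.degrees[GROUP_FREE] == 1

    def test_pruned_terms_hierarchical(self, bmi_growth_fit):
        # retained term sets are {1}, {1,t}, {1,t,t^2} or {1,t,t^2,t^3}
        for g, deg in bmi_growth_fit.degrees.items():
            for k in range(deg + 1):
                assert bmi_growth_fit.term_name(g, k) in bmi_growth_fit.coef.index
            assert bmi_growth_fit.term_name(g, deg + 1) not in bmi_growth_fit.coef.index

    def test_recovers_generating_coefficients(self, tracked_cohort, bmi_growth_fit):
        cfg, _, _, _ = tracked_cohort
        # progressive-weight-gain class has strong curvature; its retained
        # terms should approximate the generating polynomial within 3 SEs
        tbl = bmi_growth_fit.coefficient_table()
        truth = cfg.class_coef[1]
        row = tbl.loc["class_2"]
        for k in range(1, bmi_growth_fit.degrees["class_2"] + 1):
            est, se = row[f"t^{k}"], row[f"se(t^{k})"]
            assert abs(est - truth[k]) < 3 * se + 0.05

    def test_unobserved_outcome_rejected(self, tracked_cohort):
        _, dataset, _, labels = tracked_cohort
        with pytest.raises(KeyError):
            fit_growth_curve("nonexistent", dataset, labels)

    def test_log_transform_applied_to_skewed_outcomes(self, tracked_cohort):
        _, dataset, _, labels = tracked_cohort
        fit = fit_growth_curve("fasting_insulin", dataset, labels)
        assert fit.transform == "log"


class TestPredictCurve:
    def test_profile_identity_at_time_zero(self, bmi_growth_fit):
        prof = {"age_t0": 60.0, "sex": 1.0, "phase_5": 0, "phase_7": 0, "phase_9": 0}
        out = predict_curve(bmi_growth_fit, prof, "class_1", [0.0])
        expect = bmi_growth_fit.coef["class_1|t^0"]
        for name, val in prof.items():
            expect += bmi_growth_fit.coef[name] * val
        assert out["mean"].iloc[0] == pytest.approx(expect)

    def test_zero_covariance_gives_zero_width_band(self, bmi_growth_fit):
        import copy

        fit = copy.deepcopy(bmi_growth_fit)
        fit.cov.iloc[:, :] = 0.0
        prof = {"age_t0": 60.0, "sex": 1.0, "phase_5": 0, "phase_7": 0, "phase_9": 0}
        out = predict_curve(fit, prof, "class_1", [-10.0, 0.0])
        assert np.allclose(out["hi"] - out["lo"], 0.0)

    def test_unknown_group_rejected(self, bmi_growth_fit):
        with pytest.raises(KeyError):
            predict_curve(bmi_growth_fit, {}, "class_9", [0.0])

    def test_band_shrinks_with_sample_size(self):
        rng = np.random.default_rng(11)
        widths = {}
        for n_per in (100, 400):
            df = two_group_null_frame(rng, n_per=n_per)
            fit = fit_growth_curve("y", df, _labels(df), max_degree=1)
            prof = {"age_t0": 60.0, "sex": 1.0, "phase_5": 0, "phase_7": 0, "phase_9": 0}
            out = predict_curve(fit, prof, "class_1", np.linspace(-15, 0, 16))
            widths[n_per] = (out["hi"] - out["lo"]).mean()
        ratio = widths[100] / widths[400]
        assert ratio == pytest.approx(2.0, rel=0.25)  # 4x subjects -> half width

    def test_log_fit_back_transform_tracks_median(self, tracked_cohort):
        cfg, dataset, _, labels = tracked_cohort
        fit = fit_growth_curve("fasting_insulin", dataset, labels)
        prof = {
            "age_t0": cfg.age_t0_mean, "sex": 0.0,
            "phase_5": 0, "phase_7": 0, "phase_9": 1,
        }
        out = predict_curve(fit, prof, GROUP_FREE, [0.0], back_transform=True)
        # generating log-scale level for the free group at t=0 is 1.8
        assert out["mean"].iloc[0] == pytest.approx(np.exp(1.8), rel=0.15)


class TestCurveContrast:
    def test_symmetry(self, bmi_growth_fit):
        a = curve_contrast_test(bmi_growth_fit, "class_1", "class_2")
        b = curve_contrast_test(bmi_growth_fit, "class_2", "class_1")
        assert a.F_statistic == pytest.approx(b.F_statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_contrast_gives_unit_p(self, bmi_growth_fit):
        import copy

        fit = copy.deepcopy(bmi_growth_fit)
        for k in range(fit.full_degrees["class_2"] + 1):
            name2 = fit.term_name("class_2", k)
            name1 = fit.term_name("class_1", k)
            fit.full_coef[name2] = fit.full_coef.get(name1, 0.0)
        fit.full_degrees["class_2"] = fit.full_degrees["class_1"]
        ct = curve_contrast_test(fit, "class_1", "class_2")
        assert ct.F_statistic == pytest.approx(0.0, abs=1e-12)
        assert ct.p_value == 1.0

    def test_distinct_generating_curves_detected(self, bmi_growth_fit):
        ct = curve_contrast_test(bmi_growth_fit, "class_1", "class_2")
        assert ct.p_value < 0.001

    def test_large_intercept_shift_always_detected(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            df = two_group_null_frame(rng, n_per=120)
            shift = df["group_truth"] == "class_2"
            df.loc[shift, "y"] += 5 * 0.8  # 5 residual SDs
            fit = fit_growth_curve("y", df, _labels(df))
            ct = curve_contrast_test(fit, "class_1", "class_2")
            assert ct.p_value < 0.001

    def test_degrees_of_freedom_reported(self, bmi_growth_fit):
        ct = curve_contrast_test(bmi_growth_fit, "class_1", GROUP_FREE)
        full = bmi_growth_fit.full_degrees
        assert ct.df_num == max(full["class_1"], full[GROUP_FREE]) + 1
        assert ct.df_den == bmi_growth_fit.n_obs - len(bmi_growth_fit.full_coef)
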