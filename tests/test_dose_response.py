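"""4PL fitting, acceptance rules, control statistics, EC50 summary."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from holotox.dose_response import (
    DoseResponseFit,
    FourParameterLogistic,
    RejectionReason,
    assess_fit_acceptance,
    compare_to_control,
    fit_four_parameter_logistic,
    is_non_monotonic,
    summarize_ec50_across_experiments,
)
from holotox.truth import four_parameter_logistic


DOSES = np.geomspace(0.5, 512.0, 8)


def sigmoid(doses, bottom=0.0, top=100.0, ec50=10.0, hill=2.0):
    return np.asarray(four_parameter_logistic(doses, bottom, top, ec50, hill))


class TestFourParameterLogistic:
    def test_exact_model_recovery(self):
        y = sigmoid(DOSES)
        fit = fit_four_parameter_logistic(DOSES, y)
        assert abs(fit.ec50 - 10.0) / 10.0 < 1e-4
        assert fit.hill == pytest.approx(2.0, rel=1e-3)
        assert fit.top == pytest.approx(100.0, rel=1e-3)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_increasing_curve_direction_inferred(self):
        """A death-type (rising) series fits without telling the direction."""
        y = 100.0 - sigmoid(DOSES)
        fit = fit_four_parameter_logistic(DOSES, y)
        assert abs(fit.ec50 - 10.0) / 10.0 < 1e-4
        assert fit.top < fit.bottom  # zero-dose asymptote is the low end

    def test_constant_responses_fail_or_zero_r2(self):
        fit = fit_four_parameter_logistic(DOSES, np.full(8, 55.0))
        assert fit.rejection_reason is RejectionReason.fit_failed or fit.r2 <= 0.0

    def test_requires_four_distinct_positive_doses(self):
        with pytest.raises(ValueError):
            fit_four_parameter_logistic([1.0, 2.0, 4.0], [90, 50, 10])

    def test_zero_dose_points_excluded(self):
        doses = np.concatenate([[0.0], DOSES])
        y = np.concatenate([[100.0], sigmoid(DOSES)])
        fit = fit_four_parameter_logistic(doses, y)
        assert abs(fit.ec50 - 10.0) / 10.0 < 1e-4

    def test_dose_unit_rescaling_rescales_ec50_exactly(self):
        """ug/mL -> ng/mL multiplies EC50 by 1000 and changes nothing else."""
        y = sigmoid(DOSES)
        f_ug = fit_four_parameter_logistic(DOSES, y)
        f_ng = fit_four_parameter_logistic(DOSES * 1000.0, y)
        assert f_ng.ec50 / f_ug.ec50 == pytest.approx(1000.0, rel=1e-6)
        assert f_ng.hill == pytest.approx(f_ug.hill, rel=1e-6)
        assert f_ng.top == pytest.approx(f_ug.top, rel=1e-6)
        assert f_ng.bottom == pytest.approx(f_ug.bottom, abs=1e-6)

    def test_sklearn_estimator_contract(self):
        est = FourParameterLogistic()
        clone(est)
        est.fit(DOSES, sigmoid(DOSES))
        assert est.ec50_ == pytest.approx(10.0, rel=1e-4)
        pred = est.predict(DOSES)
        np.testing.assert_allclose(pred, sigmoid(DOSES), atol=1e-6)
        assert est.get_params() == {"max_nfev": 400}


class TestAcceptance:
    def test_monotone_sigmoid_accepted(self):
        y = sigmoid(DOSES)
        fit = fit_four_parameter_logistic(DOSES, y)
        fit = assess_fit_acceptance(fit, DOSES, y)
        assert fit.accepted
        assert fit.rejection_reason is RejectionReason.none

    def test_rebound_series_rejected_non_monotonic(self):
        """Dip at low dose, rebound at mid doses, drop at high dose."""
        doses = np.array([0.002, 0.02, 0.2, 2.0, 4.0, 8.0, 32.0, 512.0])
        y = np.array([100.0, 95.0, 35.0, 40.0, 75.0, 74.0, 20.0, 5.0])
        fit = fit_four_parameter_logistic(doses, y)
        fit = assess_fit_acceptance(fit, doses, y)
        assert not fit.accepted
        assert fit.rejection_reason is RejectionReason.non_monotonic

    def test_ec50_outside_tested_range_rejected(self):
        doses = np.geomspace(1.0, 8.0, 6)  # EC50 = 16 lies above the range
        y = sigmoid(doses, ec50=16.0, hill=2.0)
        fit = fit_four_parameter_logistic(doses, y)
        fit = assess_fit_acceptance(fit, doses, y)
        assert not fit.accepted
        assert fit.rejection_reason is RejectionReason.ec50_out_of_range

    def test_noise_allowance_tolerates_small_rebounds(self, rng):
        """Replicate scatter below k*SEM must not trigger rejection."""
        doses = np.repeat(DOSES, 8)
        y = sigmoid(doses) + 2.0 * rng.standard_normal(doses.size)
        assert not is_non_monotonic(doses, y, k_sem=3.0)

    def test_poor_fit_rejected(self, rng):
        y = 50.0 + 40.0 * rng.standard_normal(8)
        fit = fit_four_parameter_logistic(DOSES, y)
        fit = assess_fit_acceptance(fit, DOSES, y)
        assert not fit.accepted


class TestCompareToControl:
    def test_identical_groups_no_stars(self):
        control = np.array([100.0, 101.0, 99.0, 100.0])
        groups = {1.0: control.copy(), 10.0: control.copy()}
        table, _ = compare_to_control(groups, control)
        assert (table["stars"] == "").all()

    def test_complete_separation_three_stars(self):
        control = np.array([100.0, 100.0, 100.0])
        groups = {10.0: np.array([0.0, 0.0, 0.0])}
        table, anova_p = compare_to_control(groups, control)
        assert table["stars"].iloc[0] == "***"
        assert table["tie_flag"].iloc[0]

    def test_exact_null_zero_variance_flagged_no_stars(self):
        control = np.array([50.0, 50.0])
        groups = {1.0: np.array([50.0, 50.0])}
        table, anova_p = compare_to_control(groups, control)
        assert table["tie_flag"].iloc[0]
        assert (table["stars"] == "").all()

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            compare_to_control({1.0: np.array([1.0])}, np.array([1.0, 2.0]))

    def test_holm_adjustment_is_monotone(self, rng):
        control = 100.0 + rng.standard_normal(6)
        groups = {
            float(d): 100.0 - d + rng.standard_normal(6) for d in (1.0, 5.0, 20.0)
        }
        table, _ = compare_to_control(groups, control)
        assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()


class TestSummarize:
    @staticmethod
    def _fit(ec50, accepted=True):
        return DoseResponseFit(
            ec50=ec50,
            accepted=accepted,
            rejection_reason=RejectionReason.none
            if accepted
            else RejectionReason.non_monotonic,
        )

    def test_mean_and_sd_presentation(self):
        out = summarize_ec50_across_experiments(
            {"DHM": [self._fit(9.0), self._fit(10.0), self._fit(8.0)]}
        )
        row = out.iloc[0]
        assert row["ec50_mean"] == pytest.approx(9.0)
        assert row["ec50_sd"] == pytest.approx(1.0)
        assert row["determined"]

    def test_single_experiment_sd_not_available(self):
        out = summarize_ec50_across_experiments({"DHM": [self._fit(9.0)]})
        assert np.isnan(out.iloc[0]["ec50_sd"])
        assert out.iloc[0]["n_accepted"] == 1

    def test_all_rejected_reported_not_determined(self):
        out = summarize_ec50_across_experiments(
            {"DHM": [self._fit(9.0, accepted=False), self._fit(11.0, accepted=False)]}
        )
        row = out.iloc[0]
        assert not row["determined"]
        assert row["label"] == "not determined"
        assert np.isnan(row["ec50_mean"])
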