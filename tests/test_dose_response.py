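"""Log-logistic model evaluation, inversion, completeness and fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adjauc.dose_response import (
    BEND_RATIO,
    DoseResponseCurve,
    LogisticParams,
    bend_concentration,
    bend_level,
    concentration_at_response,
    fit_ec50_model,
    fit_ic50_model,
    fit_logistic,
    is_complete,
    predict_response,
    residual_standard_error,
)
from adjauc.errors import InsufficientDataError, NoValueError

from conftest import EIGHT_POINT, make_curve

params_st = st.builds(
    LogisticParams,
    a_min=st.floats(-30, 0),
    a_max=st.floats(30, 110),
    ec50=st.floats(0.1, 1e5),
    hill=st.floats(0.15, 8),
)


class TestCurveEvaluation:
    @pytest.mark.parametrize(
        "params, x, expected",
        [
            (LogisticParams(0, 100, 123.4, 2.7), 123.4, 50.0),  # half effect at EC50
            (LogisticParams(0, 100, 100, 1), 300, 75.0),
            (LogisticParams(-10, 90, 1000, 1), 1000, 40.0),
        ],
    )
    def test_predict_known_values(self, params, x, expected):
        assert predict_response(params, x) == pytest.approx(expected, abs=1e-9)

    def test_low_dose_limit_is_lower_asymptote(self):
        p = LogisticParams(-5, 95, 100, 1.5)
        assert predict_response(p, 1e-8) == pytest.approx(p.a_min, abs=1e-6)

    def test_nonpositive_concentration_rejected(self):
        p = LogisticParams(0, 100, 100, 1)
        with pytest.raises(ValueError):
            predict_response(p, 0.0)
        with pytest.raises(ValueError):
            predict_response(p, -5.0)

    def test_inverse_half_effect_is_ec50(self):
        p = LogisticParams(-10, 90, 777, 1.3)
        assert concentration_at_response(p, 40.0) == pytest.approx(777, rel=1e-12)

    def test_inverse_at_bend_level_matches_derivation(self):
        # response 82.3959 on the unit curve sits at ~4.6805x the EC50
        p = LogisticParams(0, 100, 1000, 1)
        assert concentration_at_response(p, 82.3959) == pytest.approx(4680.5, abs=0.5)

    def test_inverse_outside_asymptotes_rejected(self):
        p = LogisticParams(0, 100, 100, 1)
        for y in (-1.0, 0.0, 100.0, 150.0):
            with pytest.raises(ValueError):
                concentration_at_response(p, y)

    @given(params=params_st, x=st.floats(1e-3, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_predict_invert_round_trip(self, params, x):
        y = predict_response(params, x)
        margin = 1e-6 * params.amplitude  # inversion ill-conditioned at asymptotes
        if params.a_min + margin < y < params.a_max - margin:
            assert concentration_at_response(params, y) == pytest.approx(x, rel=1e-5)

    @given(params=params_st)
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, params):
        xs = np.logspace(-3, 6, 80)
        ys = predict_response(params, xs)
        assert np.all(np.diff(ys) >= -1e-9)
        assert np.all(ys >= params.a_min - 1e-9)
        assert np.all(ys <= params.a_max + 1e-9)


class TestBendPoint:
    @pytest.mark.parametrize(
        "a_min, a_max, expected",
        [
            (0.0, 100.0, -100 / (1 + BEND_RATIO) + 100),   # 82.3959...
            (-10.0, 90.0, -100 / (1 + BEND_RATIO) + 90),   # 72.3959...
            (25.0, 25.0, 25.0),                            # degenerate flat curve
        ],
    )
    def test_bend_level(self, a_min, a_max, expected):
        p = LogisticParams(a_min, a_max, 50, 1)
        assert bend_level(p) == pytest.approx(expected, abs=1e-12)

    @given(params=params_st)
    @settings(max_examples=200, deadline=None)
    def test_bend_concentration_closed_form_identity(self, params):
        # inverse-of-bend-level route must equal ec50 * 4.6805^(1/hill)
        via_inverse = concentration_at_response(params, bend_level(params))
        assert via_inverse == pytest.approx(bend_concentration(params), rel=1e-9)


class TestCompleteness:
    # tested grid from the 8-point half-log design, ~{2.5,8,25,80,250,800,2530,8000}
    def test_slow_curve_incomplete(self):
        # bend concentration 4680.5 nM: only the 8000 nM point exceeds it
        curve = make_curve(LogisticParams(0, 100, 1000, 1))
        assert not is_complete(curve, LogisticParams(0, 100, 1000, 1))

    def test_fast_curve_complete(self):
        # bend concentration 468.05 nM: 790, 2500 and 8000 nM exceed it
        curve = make_curve(LogisticParams(0, 100, 100, 1))
        assert is_complete(curve, LogisticParams(0, 100, 100, 1))

    def test_top_at_or_below_ec50_never_complete(self):
        params = LogisticParams(0, 100, float(EIGHT_POINT[-1]), 1.0)
        curve = make_curve(params)
        assert not is_complete(curve, params)

    def test_degenerate_flat_params_incomplete(self):
        curve = make_curve(LogisticParams(0, 100, 100, 1))
        assert not is_complete(curve, LogisticParams(10, 10, 100, 1))


class TestFitting:
    def test_noiseless_recovery_four_params(self):
        truth = LogisticParams(0, 100, 500, 1.2)
        fit = fit_logistic(make_curve(truth))
        assert fit.converged
        assert fit.params.a_max == pytest.approx(truth.a_max, rel=1e-3, abs=1e-3)
        assert fit.params.a_min == pytest.approx(truth.a_min, rel=1e-3, abs=1e-3)
        assert fit.params.ec50 == pytest.approx(truth.ec50, rel=1e-3)
        assert fit.params.hill == pytest.approx(truth.hill, rel=1e-3)

    def test_fixed_asymptotes_honored_exactly(self):
        curve = make_curve(LogisticParams(0, 100, 500, 1.2))
        fit = fit_logistic(curve, fixed_a_min=0.0, fixed_a_max=100.0)
        assert fit.params.a_min == 0.0
        assert fit.params.a_max == 100.0
        assert fit.n_free == 2

    def test_insufficient_distinct_concentrations(self):
        curve = DoseResponseCurve("S", "D", "C",
                                  np.array([1.0, 1.0, 10.0]),
                                  np.array([0.0, 1.0, 50.0]))
        with pytest.raises(InsufficientDataError):
            fit_logistic(curve)  # 2 distinct < 4 free
        with pytest.raises(InsufficientDataError):
            fit_ic50_model(curve)  # < 3 distinct

    def test_ic50_model_is_fit_logistic_with_both_fixed(self):
        curve = make_curve(LogisticParams(0, 60, 800, 1), noise_sd=3.0)
        via_wrapper = fit_ic50_model(curve)
        via_generic = fit_logistic(curve, fixed_a_min=0.0, fixed_a_max=100.0)
        assert via_wrapper.params == via_generic.params
        assert via_wrapper.model_kind == "IC50"

    def test_ic50_noiseless_recovery(self):
        fit = fit_ic50_model(make_curve(LogisticParams(0, 100, 800, 1)))
        assert fit.params.ec50 == pytest.approx(800, rel=1e-3)


class TestEc50Pipeline:
    def test_complete_high_amplitude_keeps_flexible_fit(self):
        truth = LogisticParams(0, 95, 100, 1.0)  # 3 points beyond the bend
        fit = fit_ec50_model(make_curve(truth))
        assert fit.complete and not fit.amplitude_refit
        assert fit.params.a_max == pytest.approx(95, rel=1e-3)
        # R_min > 0 empties the R_min <= A_min <= 0 box: a_min held at 0
        assert fit.params.a_min == 0.0
        assert fit.n_free == 3

    def test_negative_responses_free_the_lower_asymptote(self):
        # an undershooting low-dose response opens the a_min box
        y = predict_response(LogisticParams(0, 95, 100, 1.0), EIGHT_POINT)
        y[0] = -4.0
        curve = DoseResponseCurve("S", "D", "C", EIGHT_POINT, y)
        assert curve.r_min < 0
        fit = fit_logistic(curve)
        assert fit.n_free == 4
        assert curve.r_min <= fit.params.a_min <= 0.0

    def test_incomplete_curve_refit_with_upper_asymptote_100(self):
        truth = LogisticParams(0, 95, 2000, 1.0)  # bend beyond top tested dose
        fit = fit_ec50_model(make_curve(truth))
        assert not fit.complete
        assert fit.params.a_max == 100.0

    def test_low_amplitude_forces_upper_asymptote_100(self):
        truth = LogisticParams(0, 10, 50, 1.0)  # amplitude below threshold
        fit = fit_ec50_model(make_curve(truth))
        assert fit.amplitude_refit
        assert fit.params.a_max == 100.0

    def test_flat_zero_responses_handled(self):
        # no-effect curve: one of the refit rules must pin A_max at 100
        curve = DoseResponseCurve("S", "D", "C", EIGHT_POINT,
                                  np.zeros_like(EIGHT_POINT))
        fit = fit_ec50_model(curve)
        assert fit.params.a_max == 100.0

    def test_few_concentrations_skip_four_param_stage(self):
        truth = LogisticParams(0, 100, 100, 1.0)
        fit = fit_ec50_model(make_curve(truth, x=np.array([10.0, 100.0, 1000.0])))
        assert fit.params.a_max == 100.0
        assert not fit.complete

    def test_refit_rules_idempotent(self):
        for truth in (LogisticParams(0, 95, 100, 1), LogisticParams(0, 95, 2000, 1),
                      LogisticParams(0, 10, 50, 1)):
            fit = fit_ec50_model(make_curve(truth))
            # the final state triggers no further rule: either the amplitude is
            # admissible or the upper asymptote is already pinned at 100
            assert (fit.params.amplitude >= 30.0) or (fit.params.a_max == 100.0)
            if fit.params.a_max == 100.0:
                refit = fit_logistic(make_curve(truth), fixed_a_max=100.0)
                assert refit.params == fit.params


class TestResidualStandardError:
    def test_noiseless_fit_has_zero_residual_se(self):
        curve = make_curve(LogisticParams(0, 100, 500, 1.2))
        fit = fit_logistic(curve)
        assert residual_standard_error(fit, curve) == pytest.approx(0.0, abs=1e-4)

    def test_undefined_when_saturated(self):
        curve = make_curve(LogisticParams(-5, 100, 500, 1),
                           x=np.array([10.0, 100.0, 1000.0, 8000.0]))
        fit = fit_logistic(curve)  # n == p == 4
        with pytest.raises(NoValueError):
            residual_standard_error(fit, curve)

    def test_recovers_noise_scale(self, rng):
        # 16-point curves, Gaussian noise sd 5: median residual SE near 5
        x = 66000.0 / 2.0 ** np.arange(15, -1, -1)
        ses = []
        for _ in range(200):
            curve = make_curve(LogisticParams(0, 100, 500, 1), x=x,
                               noise_sd=5.0, rng=rng)
            fit = fit_ic50_model(curve)
            ses.append(residual_standard_error(fit, curve))
        assert 4.0 <= np.median(ses) <= 6.0

    def test_ic50_model_fits_cytostatic_data_worse(self):
        # plateau at 60%: the fixed 0/100 asymptotes cannot track the data
        curve = make_curve(LogisticParams(0, 60, 200, 1), noise_sd=2.0)
        se_ec50 = residual_standard_error(fit_ec50_model(curve), curve)
        se_ic50 = residual_standard_error(fit_ic50_model(curve), curve)
        assert se_ec50 < se_ic50
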