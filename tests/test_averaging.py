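"""AICc, Akaike weights, model-averaged predictions and the adjustment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tractadjust._exceptions import DegenerateWeightsError, NoValidModelError
from tractadjust.averaging import (
    aicc,
    akaike_weights,
    average_breakpoint_params,
    average_predictions,
    average_subject,
    predict_on_grid,
    residuals_and_adjust,
)
from tractadjust.models import CandidateFit, ModelParams, eval_model, fit_all

from conftest import make_table


def _fit_from_params(params, lengths, k=None):
    from tractadjust.models import K_PARAMS

    fitted = np.asarray(eval_model(params, lengths))
    return CandidateFit(
        params=params,
        lengths_mm=np.asarray(lengths, dtype=float),
        fitted=fitted,
        sum_abs_resid=1.0,
        n=len(lengths),
        k=k or K_PARAMS[params.kind],
        aicc=0.0,
    )


class TestAicc:
    def test_closed_form(self):
        # independent arithmetic: b = 1/50, loglik = -50(ln(0.04)+1)
        loglik = -50 * (math.log(2.0 / 50.0) + 1.0)
        expected = 2 * 4 - 2 * loglik + 2 * 4 * 5 / (50 - 4 - 1)
        assert aicc(1.0, 50, 4) == pytest.approx(expected, rel=1e-12)

    def test_doubling_residuals_adds_2n_log2(self):
        n, k = 40, 3
        assert aicc(2.0, n, k) - aicc(1.0, n, k) == pytest.approx(
            2 * n * math.log(2), rel=1e-12
        )

    def test_equal_objectives_give_equal_aicc(self):
        assert aicc(0.7, 30, 4) == aicc(0.7, 30, 4)

    def test_perfect_fit_sentinel(self):
        assert aicc(0.0, 30, 4) == -math.inf

    def test_small_sample_excluded_with_warning(self):
        with pytest.warns(RuntimeWarning, match="excluded"):
            assert aicc(1.0, 5, 5) == math.inf


class TestAkaikeWeights:
    def test_equal_aiccs_split_evenly(self):
        np.testing.assert_allclose(akaike_weights([3.0, 3.0, 3.0]), [1 / 3] * 3)

    def test_closed_form_with_excluded_model(self):
        w = akaike_weights([0.0, 2.0, math.inf])
        denom = 1 + math.exp(-1)
        np.testing.assert_allclose(w, [1 / denom, math.exp(-1) / denom, 0.0],
                                   atol=1e-15)

    @settings(derandomize=True, max_examples=50)
    @given(st.tuples(*[st.floats(-500, 500)] * 3))
    def test_sum_to_one_and_best_model_dominates(self, triple):
        w = akaike_weights(triple)
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all((w >= 0) & (w <= 1))
        # the smallest-AICc model carries the largest weight (ties allowed)
        assert w[np.argmin(triple)] >= w.max() - 1e-12

    def test_perfect_fit_takes_all_weight(self):
        np.testing.assert_allclose(
            akaike_weights([-math.inf, 3.0, 5.0]), [1.0, 0.0, 0.0]
        )

    def test_tied_perfect_fits_split_weight(self):
        np.testing.assert_allclose(
            akaike_weights([-math.inf, -math.inf, 5.0]), [0.5, 0.5, 0.0]
        )

    def test_all_excluded_raises(self):
        with pytest.raises(NoValidModelError):
            akaike_weights([math.inf, math.inf, math.inf])


class TestAveragePredictions:
    def test_unit_weight_returns_that_model(self):
        lengths = np.linspace(60, 150, 10)
        fits = [
            _fit_from_params(ModelParams("linear", 0.1, 0.002), lengths),
            _fit_from_params(ModelParams("blackman", 0.05, 0.004, 100.0), lengths),
            _fit_from_params(ModelParams("piecewise", 0.05, 0.004, 100.0, -0.001),
                             lengths),
        ]
        np.testing.assert_allclose(
            average_predictions(fits, [1.0, 0.0, 0.0]), fits[0].fitted
        )

    def test_half_half_average(self):
        lengths = np.array([120.0])
        bm = _fit_from_params(ModelParams("blackman", 0.0, 0.004, 100.0), lengths)
        pw = _fit_from_params(ModelParams("piecewise", 0.0, 0.0038, 100.0, 0.0),
                              lengths)
        avg = average_predictions([bm, pw], [0.5, 0.5])
        assert avg[0] == pytest.approx((bm.fitted[0] + pw.fitted[0]) / 2)

    def test_matches_brute_force_and_envelope(self, rng):
        lengths = np.sort(rng.uniform(60, 150, 15))
        fits = [
            _fit_from_params(ModelParams("linear", 0.1, 0.002), lengths),
            _fit_from_params(ModelParams("blackman", 0.05, 0.004, 100.0), lengths),
            _fit_from_params(ModelParams("piecewise", 0.05, 0.004, 95.0, -0.001),
                             lengths),
        ]
        raw = rng.random(3)
        w = raw / raw.sum()
        avg = average_predictions(fits, w)
        brute = np.array(
            [sum(w[m] * fits[m].fitted[i] for m in range(3))
             for i in range(len(lengths))]
        )
        np.testing.assert_allclose(avg, brute, atol=1e-15)
        stack = np.vstack([f.fitted for f in fits])
        assert np.all(avg >= stack.min(axis=0) - 1e-12)
        assert np.all(avg <= stack.max(axis=0) + 1e-12)

    def test_misaligned_fits_rejected(self):
        f1 = _fit_from_params(ModelParams("linear", 0.1, 0.002),
                              np.linspace(60, 150, 10))
        f2 = _fit_from_params(ModelParams("linear", 0.1, 0.002),
                              np.linspace(60, 150, 11))
        with pytest.raises(ValueError):
            average_predictions([f1, f2], [0.5, 0.5])


class TestAverageBreakpointParams:
    # the worked single-subject example: printed weights linear 0.007,
    # blackman 0.564, piecewise 0.270; inflections 103.0 / 102.0 mm with
    # values 0.390 / 0.383 there
    W = (0.007, 0.564, 0.270)

    def _fits(self):
        lengths = np.linspace(60, 150, 10)
        bm = _fit_from_params(
            ModelParams("blackman", 0.390 - 0.003 * 103.0, 0.003, 103.0), lengths
        )
        pw = _fit_from_params(
            ModelParams("piecewise", 0.383 - 0.003 * 102.0, 0.003, 102.0, 0.0006),
            lengths,
        )
        return bm, pw

    def test_worked_example_inflection(self):
        bm, pw = self._fits()
        c_bar, v_bar, s1, s2, (wb, wp) = average_breakpoint_params(bm, pw, self.W)
        assert wb + wp == pytest.approx(1.0, abs=1e-12)
        assert round(c_bar, 1) == 102.7
        assert round(v_bar, 3) == 0.388
        assert s1 == pytest.approx(0.003, abs=1e-12)

    def test_zero_piecewise_weight(self):
        bm, pw = self._fits()
        c_bar, v_bar, s1, s2, _ = average_breakpoint_params(bm, pw, (0.4, 0.6, 0.0))
        assert c_bar == bm.params.breakpoint
        assert s2 == 0.0

    def test_degenerate_weights_raise(self):
        bm, pw = self._fits()
        with pytest.raises(DegenerateWeightsError):
            average_breakpoint_params(bm, pw, (1.0, 0.0, 0.0))


class TestResidualsAndAdjust:
    def test_exact_reconstruction_and_rank_preservation(self, blackman_table):
        fits = fit_all(blackman_table)
        avg = average_subject(fits)
        adj = residuals_and_adjust(blackman_table, avg)
        np.testing.assert_allclose(
            adj.observed, avg.averaged_fitted + adj.residuals, atol=1e-12
        )
        np.testing.assert_allclose(
            adj.adjusted - adj.residuals, avg.value_at_inflection, atol=1e-12
        )
        np.testing.assert_array_equal(
            np.argsort(adj.adjusted), np.argsort(adj.residuals)
        )

    def test_zero_residual_tract_maps_to_reference(self, blackman_table):
        fits = fit_all(blackman_table)
        avg = average_subject(fits)
        table = make_table(blackman_table.lengths_mm, avg.averaged_fitted.copy())
        adj = residuals_and_adjust(table, avg)
        np.testing.assert_allclose(adj.residuals, 0.0, atol=1e-12)
        np.testing.assert_allclose(adj.adjusted, avg.value_at_inflection, atol=1e-12)

    def test_metric_shift_equivariance_after_refit(self, blackman_table):
        delta = 0.15
        shifted = make_table(
            blackman_table.lengths_mm, blackman_table.metrics + delta,
            metric_name="metric",
        )
        a0 = average_subject(fit_all(blackman_table))
        a1 = average_subject(fit_all(shifted))
        r0 = residuals_and_adjust(blackman_table, a0)
        r1 = residuals_and_adjust(shifted, a1)
        # intercepts absorb the shift: residuals ~unchanged, adjusted shifts by delta
        assert np.median(np.abs(r1.residuals - r0.residuals)) < 5e-3
        assert np.median(r1.adjusted - r0.adjusted) == pytest.approx(delta, abs=5e-3)


class TestPredictOnGrid:
    def test_grid_at_observed_lengths_matches_average_predictions(self, blackman_table):
        fits = fit_all(blackman_table)
        avg = average_subject(fits)
        preds, extrap = predict_on_grid(fits, avg.weights, blackman_table.lengths_mm)
        np.testing.assert_allclose(preds, avg.averaged_fitted, atol=1e-12)
        assert not extrap.any()

    def test_blackman_only_weights_give_flat_curve_beyond_breakpoint(self, blackman_table):
        fits = fit_all(blackman_table)
        c = fits["blackman"].params.breakpoint
        grid = np.arange(c + 1, blackman_table.lengths_mm.max(), 1.0)
        preds, _ = predict_on_grid(fits, [0.0, 1.0, 0.0], grid)
        assert np.ptp(preds) < 1e-12

    def test_extrapolation_flagged(self, blackman_table):
        fits = fit_all(blackman_table)
        avg = average_subject(fits)
        lo = blackman_table.lengths_mm.min()
        with pytest.warns(RuntimeWarning, match="outside the observed"):
            _, extrap = predict_on_grid(fits, avg.weights, [lo - 10.0, lo + 1.0])
        assert extrap.tolist() == [True, False]

    def test_empty_grid_rejected(self, blackman_table):
        fits = fit_all(blackman_table)
        with pytest.raises(ValueError):
            predict_on_grid(fits, [1 / 3] * 3, [])
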