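"""Unit and property tests for the single-fiber logarithmic law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibermech import (
    FiberLawParams,
    FiberLawRegressor,
    FitError,
    StressStrainCurve,
    evaluate_fiber_stress,
    fit_fiber_law,
    harmonic_stress,
    r_squared,
)
from fibermech.simulate import generate_synthetic_fiber_curve

law_params = st.builds(
    FiberLawParams,
    a=st.floats(1.0, 50.0),
    b=st.floats(-10.0, -0.1),
    c=st.floats(1e-5, 0.1),
)


class TestEvaluate:
    def test_log_vanishes_at_unit_argument(self, blend_fits):
        # at strain = 1 - c the bracket reduces to a for every fitted blend
        for params in blend_fits.values():
            assert evaluate_fiber_stress(params, 1.0 - params.c) == pytest.approx(
                params.a, rel=1e-12)

    def test_zero_slope_gives_constant_stress(self):
        params = FiberLawParams(a=5.0, b=0.0, c=1e-3)
        eps = np.linspace(0.0, 1.0, 7)
        assert np.allclose(evaluate_fiber_stress(params, eps), 5.0)
        negative = FiberLawParams(a=-5.0, b=0.0, c=1e-3)
        assert np.all(evaluate_fiber_stress(negative, eps) == 0.0)

    def test_clamp_at_zero_strain(self, blend_fits):
        # at eps = 0 the raw law is negative for every fitted blend: a pure-SF
        # fiber evaluates to a - b*ln(c) ~ -3.14 MPa, clamped to zero
        params = blend_fits["100/0"]
        raw = params.a - params.b * math.log(params.c)
        assert raw < 0
        assert raw == pytest.approx(-3.1398, abs=5e-4)
        assert evaluate_fiber_stress(params, 0.0) == 0.0
        assert evaluate_fiber_stress(params, 0.0, clamp=False) == pytest.approx(raw)

    @pytest.mark.parametrize("bad", [-0.1, math.nan, math.inf])
    def test_rejects_inadmissible_strain(self, bad, blend_fits):
        with pytest.raises(ValueError):
            evaluate_fiber_stress(blend_fits["100/0"], bad)

    @given(params=law_params, eps=st.floats(0.0, 1.0), delta=st.floats(1e-6, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_strain_for_negative_slope(self, params, eps, delta):
        lo = evaluate_fiber_stress(params, eps, clamp=False)
        hi = evaluate_fiber_stress(params, eps + delta, clamp=False)
        assert hi >= lo


class TestHarmonicStress:
    @given(params=law_params, eps=st.floats(0.0, 1.0), d=st.floats(10.0, 300.0))
    @settings(max_examples=100, deadline=None)
    def test_identity_when_diameter_equals_harmonic_mean(self, params, eps, d):
        assert harmonic_stress(params, eps, d, d) == pytest.approx(
            evaluate_fiber_stress(params, eps), rel=1e-12)

    def test_factor_two_at_triple_diameter(self, blend_fits):
        params = blend_fits["75/25"]
        base = evaluate_fiber_stress(params, 0.3)
        assert harmonic_stress(params, 0.3, 3 * 60.0, 60.0) == pytest.approx(
            2.0 * base, rel=1e-12)

    def test_hand_arithmetic_50_50_blend(self, blend_fits, blend_diameters):
        # independent hand evaluation of (1/2)(1+1)[a - b*ln(0.2 + c)]
        params = blend_fits["50/50"]
        D = blend_diameters["50/50"][2]
        expected = 0.5 * 2.0 * (params.a - params.b * math.log(0.2 + params.c))
        assert harmonic_stress(params, 0.2, D, D) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("d,D", [(0.0, 60.0), (-5.0, 60.0), (60.0, 0.0)])
    def test_rejects_nonpositive_diameters(self, d, D, blend_fits):
        with pytest.raises(ValueError):
            harmonic_stress(blend_fits["100/0"], 0.1, d, D)


class TestFit:
    def test_noiseless_round_trip_recovers_all_blends(self, blend_fits):
        strain = np.linspace(0.01, 1.0, 50)
        for label, truth in blend_fits.items():
            curve = StressStrainCurve(
                strain, evaluate_fiber_stress(truth, strain, clamp=False))
            fitted, r2 = fit_fiber_law(curve)
            for name in ("a", "b", "c"):
                got, want = getattr(fitted, name), getattr(truth, name)
                assert abs(got - want) / abs(want) < 1e-6, (label, name)
            assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_two_percent(self, blend_fits):
        truth = blend_fits["75/25"]
        curve = generate_synthetic_fiber_curve(truth, noise_sd=0.1, n_points=100,
                                               strain_range=(0.01, 1.0), seed=11)
        fitted, r2 = fit_fiber_law(curve)
        assert abs(fitted.a - truth.a) / truth.a < 0.02
        assert r2 > 0.95

    def test_constant_stress_curve_raises(self):
        curve = StressStrainCurve(np.linspace(0.0, 1.0, 10), np.full(10, 3.0))
        with pytest.raises(FitError, match="constant"):
            fit_fiber_law(curve)

    def test_too_few_points_raises(self):
        curve = StressStrainCurve([0.0, 0.1, 0.2], [0.0, 1.0, 2.0])
        with pytest.raises(FitError, match="4 distinct"):
            fit_fiber_law(curve)

    def test_initial_guess_is_respected_deterministically(self, blend_fits):
        truth = blend_fits["0/100"]
        strain = np.linspace(0.01, 1.0, 40)
        curve = StressStrainCurve(strain,
                                  evaluate_fiber_stress(truth, strain, clamp=False))
        guess = FiberLawParams(a=10.0, b=-1.0, c=1e-2)
        first, _ = fit_fiber_law(curve, guess)
        second, _ = fit_fiber_law(curve, guess)
        assert (first.a, first.b, first.c) == (second.a, second.b, second.c)


class TestRSquared:
    def test_perfect_fit_is_one(self, blend_fits):
        params = blend_fits["25/75"]
        strain = np.linspace(0.01, 0.8, 30)
        curve = StressStrainCurve(strain,
                                  evaluate_fiber_stress(params, strain, clamp=False))
        assert r_squared(curve, params) == pytest.approx(1.0, abs=1e-14)

    def test_mean_only_model_is_zero(self):
        strain = np.linspace(0.0, 1.0, 20)
        stress = np.linspace(1.0, 5.0, 20)
        mean_model = FiberLawParams(a=float(np.mean(stress)), b=0.0, c=1.0)
        curve = StressStrainCurve(strain, stress)
        assert r_squared(curve, mean_model) == pytest.approx(0.0, abs=1e-14)

    def test_matches_direct_two_pass_summation(self, blend_fits):
        params = blend_fits["50/50"]
        curve = generate_synthetic_fiber_curve(params, noise_sd=0.5, n_points=60,
                                               strain_range=(0.02, 0.9), seed=5)
        predicted = params.a - params.b * np.log(curve.strain + params.c)
        ss_res = sum((s - p) ** 2 for s, p in zip(curve.stress, predicted))
        ss_tot = sum((s - np.mean(curve.stress)) ** 2 for s in curve.stress)
        assert r_squared(curve, params) == pytest.approx(1.0 - ss_res / ss_tot,
                                                         rel=1e-12)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_stress_unit_rescaling(self, scale):
        params = FiberLawParams(a=20.0, b=-3.0, c=1e-3)
        curve = generate_synthetic_fiber_curve(params, noise_sd=0.3, n_points=40,
                                               strain_range=(0.05, 0.8), seed=7)
        scaled_curve = StressStrainCurve(curve.strain, curve.stress * scale)
        scaled_params = FiberLawParams(a=params.a * scale, b=params.b * scale,
                                       c=params.c)
        assert r_squared(scaled_curve, scaled_params) == pytest.approx(
            r_squared(curve, params), rel=1e-9)

    def test_zero_variance_stress_raises(self):
        curve = StressStrainCurve([0.0, 0.5, 1.0], [2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="variance"):
            r_squared(curve, FiberLawParams(a=2.0, b=0.0, c=1.0))


class TestParamsAndCurveValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(a=1.0, b=1.0, c=0.0),
        dict(a=1.0, b=1.0, c=-1e-3),
        dict(a=math.nan, b=1.0, c=1.0),
        dict(a=1.0, b=math.inf, c=1.0),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FiberLawParams(**kwargs)

    @pytest.mark.parametrize("strain,stress", [
        ([0.0, 0.1], [1.0]),              # length mismatch
        ([0.2, 0.1], [1.0, 2.0]),         # decreasing strain
        ([-0.1, 0.1], [1.0, 2.0]),        # negative strain
        ([0.0, math.nan], [1.0, 2.0]),    # non-finite
        ([], []),                         # empty
    ])
    def test_invalid_curves_rejected(self, strain, stress):
        with pytest.raises(ValueError):
            StressStrainCurve(np.asarray(strain, dtype=float),
                              np.asarray(stress, dtype=float))


class TestRegressor:
    def test_fit_predict_round_trip(self, blend_fits):
        truth = blend_fits["100/0"]
        strain = np.linspace(0.01, 1.0, 50)
        stress = evaluate_fiber_stress(truth, strain, clamp=False)
        reg = FiberLawRegressor(clamp=False).fit(strain.reshape(-1, 1), stress)
        assert reg.a_ == pytest.approx(truth.a, rel=1e-6)
        assert reg.b_ == pytest.approx(truth.b, rel=1e-6)
        assert reg.c_ == pytest.approx(truth.c, rel=1e-6)
        assert reg.r_squared_ == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(reg.predict(strain.reshape(-1, 1)), stress)

    def test_sklearn_contract(self):
        from sklearn.base import clone

        reg = FiberLawRegressor(clamp=False)
        cloned = clone(reg)
        assert cloned.get_params() == reg.get_params()
        reg.set_params(clamp=True)
        assert reg.get_params()["clamp"] is True
        with pytest.raises(AttributeError):
            FiberLawRegressor().predict([[0.1]])

    def test_score_is_high_on_noisy_data(self, blend_fits):
        truth = blend_fits["50/50"]
        curve = generate_synthetic_fiber_curve(truth, noise_sd=0.1, n_points=80,
                                               strain_range=(0.01, 1.0), seed=3)
        reg = FiberLawRegressor().fit(curve.strain, curve.stress)
        assert reg.score(curve.strain.reshape(-1, 1), curve.stress) > 0.95
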