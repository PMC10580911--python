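"""Unit and property tests for the tight slow-binding progress-curve module."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tightbind.errors import DataError, DomainError, FitError
from tightbind.progress import (
    ProgressCurve, binding_roots, eval_progress_model, fit_progress_curve,
    fit_uninhibited, gamma_of, henderson_ki, morrison_fraction,
    normalize_endpoint,
)
from tightbind.simulate import ZERO_NOISE, SimNoise, simulate_progress_curve

nM = 1e-9


class TestGamma:
    def test_no_inhibition_gives_zero(self):
        assert gamma_of(2 * nM, 8 * nM, 1.0, 1.0) == 0.0

    def test_complete_inhibition_at_equimolarity_is_boundary_error(self):
        # Et*(1-0)^2/It = 1 at Et == It: ln(0) in the model, must raise
        with pytest.raises(DomainError):
            gamma_of(2 * nM, 2 * nM, 1.0, 0.0)

    def test_equals_root_ratio_of_binding_quadratic(self):
        # gamma = Et(1-vs/v0)^2/It must equal x1/x2 exactly when vs/v0 is
        # the Morrison steady state (independent quadratic-root oracle)
        Et, It, ki = 2 * nM, 8 * nM, 0.33 * nM
        frac = morrison_fraction(Et, It, ki)
        x1, x2 = binding_roots(Et, It, ki)
        assert gamma_of(Et, It, 1.0, frac) == pytest.approx(x1 / x2, rel=1e-12)

    @pytest.mark.parametrize("Et,It,v0,vs", [
        (0.0, 1 * nM, 1.0, 0.5), (1 * nM, 0.0, 1.0, 0.5),
        (1 * nM, 1 * nM, 0.0, 0.0), (1 * nM, 1 * nM, 1.0, 1.5),
    ])
    def test_domain_errors(self, Et, It, v0, vs):
        with pytest.raises(DomainError):
            gamma_of(Et, It, v0, vs)


class TestMorrison:
    def test_no_inhibitor(self):
        assert morrison_fraction(2 * nM, 0.0, 0.33 * nM) == 1.0

    def test_excess_inhibitor_oracle(self):
        # brute-force root of the quadratic: x1 ~ 1.9507 nM
        b = (2 + 15 + 0.33) * nM
        x1 = min(np.roots([1.0, -b, 2 * nM * 15 * nM]).real)
        expected = (2 * nM - x1) / (2 * nM)
        got = morrison_fraction(2 * nM, 15 * nM, 0.33 * nM)
        assert got == pytest.approx(expected, rel=1e-10)
        assert got == pytest.approx(0.025, abs=0.001)

    def test_classical_limit_at_vanishing_enzyme(self):
        # Et -> 0: vs/v0 -> 1/(1 + It/Ki) = 0.5 at It = Ki
        frac = morrison_fraction(1e-15, 1 * nM, 1 * nM)
        assert frac == pytest.approx(0.5, rel=1e-6)

    def test_strictly_decreasing_in_inhibitor(self):
        its = np.linspace(0.1, 20, 25) * nM
        fr = [morrison_fraction(2 * nM, i, 0.33 * nM) for i in its]
        assert np.all(np.diff(fr) < 0)

    def test_strictly_increasing_in_ki(self):
        kis = np.logspace(-2, 2, 25) * nM
        fr = [morrison_fraction(2 * nM, 4 * nM, k) for k in kis]
        assert np.all(np.diff(fr) > 0)

    @settings(derandomize=True, max_examples=50)
    @given(Et=st.floats(0.1, 100), It=st.floats(0.1, 100),
           ki=st.floats(1e-3, 1e3))
    def test_fraction_in_unit_interval(self, Et, It, ki):
        frac = morrison_fraction(Et * nM, It * nM, ki * nM)
        assert 0.0 < frac <= 1.0


class TestProgressModel:
    def test_at_time_zero_returns_baseline(self):
        assert eval_progress_model(1e-3, 1e-4, 1e-2, 0.123, 0.4, 0.0) == \
            pytest.approx(0.123, abs=1e-15)

    def test_continuity_at_gamma_zero(self):
        for t in (10.0, 100.0, 1000.0):
            tiny = eval_progress_model(1e-3, 1e-4, 1e-2, 0.05, 1e-12, t)
            limit = eval_progress_model(1e-3, 1e-4, 1e-2, 0.05, 0.0, t)
            assert tiny == pytest.approx(limit, abs=1e-8)

    def test_gamma_domain_enforced(self):
        with pytest.raises(DomainError):
            eval_progress_model(1e-3, 1e-4, 1e-2, 0.05, 1.0, 10.0)


class TestFitProgressCurve:
    def test_noiseless_recovery(self, fx_progress_25):
        fx = fx_progress_25
        des = fx.make_progress_design(4 * nM)
        from tightbind.progress import SlowBindingParams
        par = SlowBindingParams(fx.truth["kon_app"],
                                fx.truth["kon_app"] * fx.truth["ki_app"])
        curve = simulate_progress_curve(par, des)
        fit = fit_progress_curve(curve, des.total_enzyme)
        x1, x2 = binding_roots(des.total_enzyme, 4 * nM, fx.truth["ki_app"])
        v0 = des.uninhibited_rate
        assert fit.converged
        assert fit.v0 == pytest.approx(v0, rel=1e-3)
        assert fit.vs == pytest.approx(v0 * (des.total_enzyme - x1)
                                       / des.total_enzyme, rel=1e-3)
        assert fit.k == pytest.approx(fx.truth["kon_app"] * (x2 - x1), rel=1e-3)

    def test_noisy_recovery_within_ten_percent(self, fx_progress_25):
        fx = fx_progress_25
        des = fx.make_progress_design(4 * nM)
        from tightbind.progress import SlowBindingParams
        par = SlowBindingParams(fx.truth["kon_app"],
                                fx.truth["kon_app"] * fx.truth["ki_app"])
        curve = simulate_progress_curve(par, des, SimNoise(seed=1))
        fit = fit_progress_curve(curve, des.total_enzyme)
        x1, x2 = binding_roots(des.total_enzyme, 4 * nM, fx.truth["ki_app"])
        v0 = des.uninhibited_rate
        vs = v0 * (des.total_enzyme - x1) / des.total_enzyme
        k = fx.truth["kon_app"] * (x2 - x1)
        for got, want in ((fit.v0, v0), (fit.vs, vs), (fit.k, k)):
            assert abs(got - want) / want < 0.10

    def test_uninhibited_trace_flags_k_unidentifiable(self):
        t = np.arange(0, 600, 2.0)
        curve = ProgressCurve("line", 1 * nM, t, 0.05 + 2e-4 * t)
        fit = fit_progress_curve(curve, 2 * nM)
        assert fit.converged
        assert fit.vs / fit.v0 >= 0.999
        assert not fit.k_identifiable

    def test_inhibitor_free_curve_rejected(self):
        t = np.arange(0, 100, 2.0)
        curve = ProgressCurve("c", 0.0, t, 0.05 + 1e-4 * t)
        with pytest.raises(FitError):
            fit_progress_curve(curve, 2 * nM)

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            ProgressCurve("c", 1 * nM, np.arange(5.0), np.arange(5.0))


class TestFitUninhibited:
    def test_exact_line(self):
        t = np.arange(0, 200, 2.0)
        curve = ProgressCurve("ref", 0.0, t, 0.02 + 5e-4 * t)
        assert fit_uninhibited(curve) == pytest.approx(5e-4, rel=1e-12)

    def test_simulated_trace_matches_analytic_rate(self, fx_progress_25):
        des = fx_progress_25.make_progress_design(0.0)
        from tightbind.progress import SlowBindingParams
        par = SlowBindingParams(1e6, 1e-4)
        curve = simulate_progress_curve(par, des)
        v0 = fit_uninhibited(curve, des)
        expect = (des.product_extinction * des.path_length * des.kcat
                  * des.total_enzyme * des.substrate_conc
                  / (des.km + des.substrate_conc))
        assert v0 == pytest.approx(expect, rel=1e-3)

    def test_constant_signal_errors(self):
        t = np.arange(0, 100, 2.0)
        curve = ProgressCurve("flat", 0.0, t, np.full_like(t, 0.3))
        with pytest.raises(DataError):
            fit_uninhibited(curve)


class TestHenderson:
    @staticmethod
    def _exact_fits(Et, ki, its):
        from tightbind.progress import ProgressFitResult
        fits = []
        for it in its:
            frac = morrison_fraction(Et, it, ki)
            fits.append(ProgressFitResult(
                curve_id=f"{it}", inhibitor_conc=it, v0=1.0, vs=frac,
                k=1e-3, A0=0.0, gamma=gamma_of(Et, it, 1.0, frac),
                residual_rms=0.0, converged=True, n_points=100))
        return fits

    def test_exact_on_morrison_steady_states(self):
        Et, ki = 2 * nM, 0.33 * nM
        fits = self._exact_fits(Et, ki, [1 * nM, 2 * nM, 4 * nM, 8 * nM])
        res = henderson_ki(fits, Et)
        assert res.ki_app == pytest.approx(ki, rel=1e-10)
        assert res.intercept == pytest.approx(Et, rel=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_forcing_through_origin_biases_slope_upward(self):
        # the Henderson line has intercept Et > 0; dropping it inflates
        # the slope estimate on exact data
        Et, ki = 2 * nM, 0.33 * nM
        fits = self._exact_fits(Et, ki, [1 * nM, 2 * nM, 4 * nM, 8 * nM])
        x = np.array([f.v0 / f.vs for f in fits])
        y = np.array([f.inhibitor_conc / (1 - f.vs / f.v0) for f in fits])
        slope_origin = np.sum(x * y) / np.sum(x * x)
        assert slope_origin > ki

    def test_exactness_on_parameter_grid(self):
        # Eq-2 consistency + Henderson identity across a coarse grid
        for Et in np.array([0.5, 2, 8]) * nM:
            for ki in np.array([0.05, 0.33, 2.0]) * nM:
                its = np.array([1, 2, 4, 8]) * nM
                fits = self._exact_fits(Et, ki, its)
                res = henderson_ki(fits, Et)
                assert res.ki_app == pytest.approx(ki, rel=1e-8)
                assert res.intercept == pytest.approx(Et, rel=1e-8)

    def test_duplicate_inhibitor_concentration_rejected(self):
        Et, ki = 2 * nM, 0.33 * nM
        fits = self._exact_fits(Et, ki, [4 * nM, 4 * nM])
        with pytest.raises(FitError):
            henderson_ki(fits, Et)

    def test_uninhibited_like_fit_excluded_with_warning(self):
        import warnings as w
        from tightbind.progress import ProgressFitResult
        Et, ki = 2 * nM, 0.33 * nM
        fits = self._exact_fits(Et, ki, [1 * nM, 2 * nM, 4 * nM])
        fits.append(ProgressFitResult("free", 8 * nM, 1.0, 1.0, 1e-3, 0.0,
                                      0.0, 0.0, True, 100))
        with w.catch_warnings(record=True) as rec:
            w.simplefilter("always")
            res = henderson_ki(fits, Et)
        assert res.n_curves == 3
        assert any("excluded" in str(r.message) for r in rec)


class TestNormalizeEndpoint:
    def _curve(self, final, It=0.0, cid="c"):
        t = np.arange(0, 100, 2.0)
        return ProgressCurve(cid, It, t, 0.01 + (final - 0.01) * t / t[-1])

    def test_self_normalization_is_zero_inhibition(self):
        ref = self._curve(0.8)
        _, pct = normalize_endpoint(ref, ref)
        assert pct == pytest.approx(0.0, abs=1e-12)

    def test_half_final_signal_is_fifty_percent(self):
        ref = self._curve(0.8)
        test = self._curve(0.4, It=4 * nM)
        _, pct = normalize_endpoint(test, ref)
        assert pct == pytest.approx(50.0, rel=1e-6)

    def test_flat_reference_rejected(self):
        t = np.arange(0, 100, 2.0)
        ref = ProgressCurve("flat", 0.0, t, np.full_like(t, 0.3))
        with pytest.raises(DataError):
            normalize_endpoint(ref, ref)

    def test_percent_inhibition_monotone_in_inhibitor(self, fx_progress_25,
                                                      zero_noise):
        from tightbind.simulate import simulate_inhibition_series
        curves = simulate_inhibition_series(fx_progress_25, zero_noise)
        ref = curves[0]
        pcts = [normalize_endpoint(c, ref)[1] for c in curves[1:]]
        assert np.all(np.diff(pcts) > 0)
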