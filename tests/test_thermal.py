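"""Thermal-response fitting, family comparison and peak extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chumrun.errors import FitError
from chumrun.thermal import (
    ResponseFit,
    ThermalResponseRegressor,
    compare_families,
    fit_response,
    peak_temperature,
)


def bins_frame(x, y):
    return pd.DataFrame({"bin_left": np.asarray(x) - 0.5, "volume": y})


class TestPolynomialFit:
    def test_exact_quadratic_recovered(self):
        x = np.arange(12.0, 25.0)
        y = 0.1 + 0.04 * x - 0.001 * x**2
        reg = ThermalResponseRegressor("polynomial").fit(x, y)
        assert reg.coef_["b1"] == pytest.approx(0.1, abs=1e-8)
        assert reg.coef_["b2"] == pytest.approx(0.04, abs=1e-8)
        assert reg.coef_["b3"] == pytest.approx(-0.001, abs=1e-8)
        assert reg.mse_ == pytest.approx(0.0, abs=1e-12)

    def test_flat_response(self):
        x = np.arange(10.0, 20.0)
        reg = ThermalResponseRegressor("polynomial").fit(x, np.full(10, 0.3))
        assert reg.coef_["b1"] == pytest.approx(0.3, abs=1e-8)
        assert reg.coef_["b2"] == pytest.approx(0.0, abs=1e-8)
        assert reg.coef_["b3"] == pytest.approx(0.0, abs=1e-8)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(10, 25, size=12))
        y = rng.uniform(0, 0.5, size=12)
        reg = ThermalResponseRegressor("polynomial").fit(x, y)
        design = np.column_stack([np.ones_like(x), x, x * x])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        assert [reg.coef_["b1"], reg.coef_["b2"], reg.coef_["b3"]] == pytest.approx(
            oracle.tolist(), abs=1e-8
        )

    def test_pvalues_match_reference_t_computation(self):
        """Coefficient p-values agree with a from-scratch t-distribution
        computation on a fixed small example to 1e-6."""
        from scipy import stats

        x = np.arange(14.0, 23.0)
        rng = np.random.default_rng(42)
        y = 0.2 + 0.03 * x - 0.002 * x**2 + rng.normal(0, 0.01, size=x.size)
        reg = ThermalResponseRegressor("polynomial").fit(x, y)
        design = np.column_stack([np.ones_like(x), x, x * x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        resid = y - design @ beta
        df = x.size - 3
        sigma2 = resid @ resid / df
        cov = sigma2 * np.linalg.inv(design.T @ design)
        for i, name in enumerate(("b1", "b2", "b3")):
            t = beta[i] / np.sqrt(cov[i, i])
            p_ref = 2 * stats.t.sf(abs(t), df=df)
            assert reg.pvalues_[name] == pytest.approx(p_ref, abs=1e-6)

    def test_too_few_bins_rejected(self):
        with pytest.raises(FitError, match="bins"):
            ThermalResponseRegressor("polynomial").fit([1.0, 2.0, 3.0], [1, 2, 3])


class TestNonlinearFamilies:
    def test_exponential_exact_recovery(self):
        x = np.arange(12.0, 24.0)
        y = 0.01 * np.exp(0.2 * x)
        reg = ThermalResponseRegressor("exponential").fit(x, y)
        assert reg.coef_["a"] == pytest.approx(0.01, rel=1e-6)
        assert reg.coef_["b"] == pytest.approx(0.2, rel=1e-6)

    def test_logistic_exact_recovery(self):
        x = np.arange(12.0, 24.0)
        y = 0.8 / (1 + np.exp(-1.1 * (x - 18.0)))
        reg = ThermalResponseRegressor("logistic").fit(x, y)
        assert reg.coef_["L"] == pytest.approx(0.8, rel=1e-5)
        assert reg.coef_["x0"] == pytest.approx(18.0, rel=1e-5)

    def test_saturating_curve_prefers_logistic_over_polynomial(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.arange(12.0, 25.0)
            y = 0.6 / (1 + np.exp(-0.9 * (x - 18.0))) + rng.normal(0, 0.01, x.size)
            fits = [
                fit_response(bins_frame(x, np.clip(y, 1e-6, None)), fam)
                for fam in ("polynomial", "logistic")
            ]
            wins += compare_families(fits).family == "logistic"
        assert wins > 10

    def test_concave_bump_prefers_polynomial(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = np.arange(13.0, 24.0)
            y = np.clip(
                0.5 - 0.02 * (x - 18.5) ** 2 + rng.normal(0, 0.01, x.size), 1e-6, None
            )
            fits = [
                fit_response(bins_frame(x, y), fam)
                for fam in ("polynomial", "exponential", "logistic")
            ]
            wins += compare_families(fits).family == "polynomial"
        assert wins >= 18


class TestComparison:
    def test_aic_invariant_to_bin_order(self):
        rng = np.random.default_rng(5)
        x = np.arange(12.0, 24.0)
        y = rng.uniform(0.01, 0.4, size=x.size)
        frame = bins_frame(x, y)
        shuffled = frame.sample(frac=1.0, random_state=1)
        for fam in ("polynomial", "exponential", "logistic"):
            a = fit_response(frame, fam)
            b = fit_response(shuffled, fam)
            assert a.aic == pytest.approx(b.aic, abs=1e-6)

    def test_single_candidate_flagged(self):
        fit = ResponseFit(
            family="polynomial", coefficients={}, se={}, pvalues={},
            mse=0.001, aic=-10.0, loglik=8.0, n_bins=10,
        )
        out = compare_families([fit])
        assert "single-candidate" in out.flags

    def test_no_candidates_rejected(self):
        with pytest.raises(FitError):
            compare_families([])

    def test_high_mse_flagged_against_benchmark(self):
        rng = np.random.default_rng(2)
        x = np.arange(12.0, 24.0)
        y = rng.uniform(0.0, 0.5, size=x.size)  # unstructured: large residuals
        fit = fit_response(bins_frame(x, np.clip(y, 1e-6, None)), "polynomial")
        assert fit.mse > 0.002
        assert any(f.startswith("mse>") for f in fit.flags)


class TestPeakTemperature:
    def test_analytic_vertex(self):
        fit = ResponseFit(
            family="polynomial",
            coefficients={"b1": 0.0, "b2": 4.2, "b3": -0.105},
            se={}, pvalues={}, mse=0.0, aic=0.0, loglik=0.0, n_bins=10,
        )
        assert peak_temperature(fit) == pytest.approx(20.0)

    def test_symmetric_vertex_at_zero(self):
        fit = ResponseFit(
            family="polynomial",
            coefficients={"b1": 0.0, "b2": 0.0, "b3": -1.0},
            se={}, pvalues={}, mse=0.0, aic=0.0, loglik=0.0, n_bins=10,
        )
        assert peak_temperature(fit) == pytest.approx(0.0)

    def test_convex_fit_has_no_interior_peak(self):
        fit = ResponseFit(
            family="polynomial",
            coefficients={"b1": 0.0, "b2": 1.0, "b3": 0.5},
            se={}, pvalues={}, mse=0.0, aic=0.0, loglik=0.0, n_bins=10,
        )
        with pytest.raises(FitError, match="peak"):
            peak_temperature(fit)

    def test_non_polynomial_rejected(self):
        fit = ResponseFit(
            family="logistic", coefficients={}, se={}, pvalues={},
            mse=0.0, aic=0.0, loglik=0.0, n_bins=10,
        )
        with pytest.raises(FitError):
            peak_temperature(fit)

    def test_peak_error_shrinks_as_bin_noise_vanishes(self):
        x = np.arange(13.0, 24.0)
        true_peak = 18.5
        errors = []
        for sd in (0.02, 0.005, 0.001):
            errs = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                y = np.clip(
                    0.45 - 0.015 * (x - true_peak) ** 2 + rng.normal(0, sd, x.size),
                    1e-9, None,
                )
                fit = fit_response(bins_frame(x, y), "polynomial")
                errs.append(abs(peak_temperature(fit) - true_peak))
            errors.append(np.mean(errs))
        assert errors[2] < errors[0]
        assert errors[2] < 0.05
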