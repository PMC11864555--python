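"""Thermal-response curves: migration volume as a function of SST.

Normalized migration volume per 1 °C SST bin is regressed on bin-center
temperature under three candidate families:

* polynomial  y = b1 + b2*x + b3*x**2   (quadratic; the vertex -b2/(2*b3)
  is the peak migration temperature when b3 < 0)
* exponential y = a * exp(b*x)
* logistic    y = L / (1 + exp(-k*(x - x0)))

Families are compared by AIC from the Gaussian log-likelihood of residuals
with the error variance estimated by ML (so the variance counts as a
parameter and AIC is comparable across families); MSE is reported alongside,
flagged when it exceeds the 0.002 reporting benchmark.  Nonlinear fits use
deterministic multi-start initialization to avoid silent local minima.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitError

FAMILIES = ("polynomial", "exponential", "logistic")
MSE_BENCHMARK = 0.002  # reporting benchmark on the 0-1 volume scale

#: parameter names per family
_PARAM_NAMES = {
    "polynomial": ("b1", "b2", "b3"),
    "exponential": ("a", "b"),
    "logistic": ("L", "k", "x0"),
}


def _exponential(x, a, b):
    return a * np.exp(b * x)


def _logistic(x, L, k, x0):
    return L / (1.0 + np.exp(-k * (x - x0)))


def _gaussian_ml_aic(rss: float, n: int, n_params: int) -> tuple[float, float]:
    """(log-likelihood, aic) with sigma^2 = rss/n; k counts sigma^2."""
    sigma2 = max(rss / n, 1e-300)
    llf = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    k = n_params + 1
    return llf, 2.0 * k - 2.0 * llf


class ThermalResponseRegressor(RegressorMixin, BaseEstimator):
    """Least-squares fit of one response family to (temperature, volume) data.

    Parameters
    ----------
    family : {"polynomial", "exponential", "logistic"}
    n_starts : int
        Number of deterministic starting points for the nonlinear families.

    Attributes (after fit)
    ----------------------
    coef_ : dict of parameter name -> estimate
    se_, pvalues_ : dicts of the same shape (t reference, df = n - p)
    mse_, aic_, loglik_, n_obs_ : fit statistics
    """

    def __init__(self, family: str = "polynomial", n_starts: int = 5):
        self.family = family
        self.n_starts = n_starts

    # -- fitting --------------------------------------------------------------

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if self.family not in FAMILIES:
            raise FitError(f"unknown family {self.family!r}; know {FAMILIES}")
        names = _PARAM_NAMES[self.family]
        n_params = len(names)
        if x.size < n_params + 1:
            raise FitError(
                f"{self.family}: need >= {n_params + 1} bins, have {x.size}"
            )
        if self.family == "polynomial":
            params, cov = self._fit_polynomial(x, y)
        else:
            params, cov = self._fit_nonlinear(x, y)
        resid = y - self._predict_params(x, params)
        rss = float(resid @ resid)
        n = x.size
        self.coef_ = dict(zip(names, (float(v) for v in params)))
        df = max(n - n_params, 1)
        sigma2_hat = rss / df
        if cov is None:
            se = np.full(n_params, np.nan)
        elif self.family == "polynomial":
            se = np.sqrt(np.diag(cov) * sigma2_hat)
        else:
            se = np.sqrt(np.diag(cov))
        self.se_ = dict(zip(names, (float(v) for v in se)))
        pv = {}
        for name, est, s in zip(names, params, se):
            if not np.isfinite(s) or s == 0.0:
                pv[name] = float("nan") if not np.isfinite(s) else (1.0 if est == 0 else 0.0)
            else:
                pv[name] = float(2.0 * stats.t.sf(abs(est / s), df=df))
        self.pvalues_ = pv
        self.mse_ = rss / n
        self.loglik_, self.aic_ = _gaussian_ml_aic(rss, n, n_params)
        self.n_obs_ = n
        return self

    def _fit_polynomial(self, x, y):
        design = np.column_stack([np.ones_like(x), x, x * x])
        params, *_ = np.linalg.lstsq(design, y, rcond=None)
        xtx = design.T @ design
        try:
            cov_unscaled = np.linalg.inv(xtx)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"polynomial design singular: {exc}") from exc
        return params, cov_unscaled

    def _starts(self, x, y) -> list[np.ndarray]:
        """Deterministic starting points spanning the data range."""
        xr = float(x.max() - x.min()) or 1.0
        ymax = float(np.abs(y).max()) or 1.0
        if self.family == "exponential":
            rates = np.linspace(-4.0 / xr, 4.0 / xr, self.n_starts)
            starts = []
            for b in rates:
                denom = float(np.mean(np.exp(b * x)))
                starts.append(np.array([float(np.mean(y)) / denom, b]))
            return starts
        # logistic: spread x0 across the range, try both slope signs
        qs = np.linspace(0.25, 0.75, max(self.n_starts - 2, 1))
        starts = [
            np.array([ymax, 4.0 / xr, float(np.quantile(x, q))]) for q in qs
        ]
        starts.append(np.array([ymax, -4.0 / xr, float(np.quantile(x, 0.5))]))
        starts.append(np.array([2.0 * ymax, 1.0 / xr, float(np.quantile(x, 0.5))]))
        return starts[: self.n_starts]

    def _fit_nonlinear(self, x, y):
        func: Callable = _exponential if self.family == "exponential" else _logistic
        best: Optional[tuple[float, np.ndarray, np.ndarray]] = None
        for p0 in self._starts(x, y):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = optimize.curve_fit(
                        func, x, y, p0=p0, maxfev=20000
                    )
                resid = y - func(x, *popt)
                rss = float(resid @ resid)
                if np.isfinite(rss) and (best is None or rss < best[0]):
                    best = (rss, popt, pcov)
            except (RuntimeError, optimize.OptimizeWarning, ValueError):
                continue
        if best is None:
            raise FitError(f"{self.family} fit failed to converge from any start")
        return best[1], best[2]

    # -- prediction -----------------------------------------------------------

    def _predict_params(self, x, params):
        if self.family == "polynomial":
            b1, b2, b3 = params
            return b1 + b2 * x + b3 * x * x
        if self.family == "exponential":
            return _exponential(x, *params)
        return _logistic(x, *params)

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        params = np.array([self.coef_[n] for n in _PARAM_NAMES[self.family]])
        return self._predict_params(x, params)

    @property
    def peak_temperature_(self) -> float:
        fitref = ResponseFit(
            family=self.family, coefficients=self.coef_, se=self.se_,
            pvalues=self.pvalues_, mse=self.mse_, aic=self.aic_,
            loglik=self.loglik_, n_bins=self.n_obs_,
        )
        return peak_temperature(fitref)


@dataclass
class ResponseFit:
    """One family's fit to a (region, regime) binned-volume set."""

    family: str
    coefficients: dict
    se: dict
    pvalues: dict
    mse: float
    aic: float
    loglik: float
    n_bins: int
    region: str = ""
    regime: str = ""
    location: str = ""
    converged: bool = True
    flags: list = field(default_factory=list)


def fit_response(
    bins: pd.DataFrame,
    family: str,
    bin_width: float = 1.0,
    drop_zero_volume: bool = True,
) -> ResponseFit:
    """Fit one family to a (bin_left, volume) table.

    Regression abscissae are bin centers (left edge + width/2).  Bins with
    zero accumulated volume are dropped by default: a temperature range with
    no recorded catch is indistinguishable from one the run never visited,
    and anchoring the curve at zero there biases it toward unvisited
    temperatures.
    """
    frame = bins.copy()
    if drop_zero_volume:
        frame = frame[frame["volume"] > 0]
    x = frame["bin_left"].to_numpy(dtype=float) + bin_width / 2.0
    y = frame["volume"].to_numpy(dtype=float)
    reg = ThermalResponseRegressor(family=family).fit(x, y)
    flags = []
    if reg.mse_ > MSE_BENCHMARK:
        flags.append(f"mse>{MSE_BENCHMARK}")
    return ResponseFit(
        family=family,
        coefficients=reg.coef_,
        se=reg.se_,
        pvalues=reg.pvalues_,
        mse=reg.mse_,
        aic=reg.aic_,
        loglik=reg.loglik_,
        n_bins=reg.n_obs_,
        region=str(bins["region"].iloc[0]) if "region" in bins else "",
        regime=str(bins["regime"].iloc[0]) if "regime" in bins else "",
        flags=flags,
    )


def compare_families(fits: Sequence[ResponseFit]) -> ResponseFit:
    """Minimal-AIC family among converged fits on the same bins.

    A single converged candidate is returned with a ``single-candidate``
    flag; AIC ties break toward fewer parameters, then family order.
    """
    fits = [f for f in fits if f.converged]
    if not fits:
        raise FitError("no converged response fits to compare")
    if len(fits) == 1:
        only = fits[0]
        if "single-candidate" not in only.flags:
            only.flags.append("single-candidate")
        return only
    order = {name: i for i, name in enumerate(FAMILIES)}
    return min(
        fits, key=lambda f: (f.aic, len(f.coefficients), order.get(f.family, 99))
    )


def family_comparison_table(fits: Sequence[ResponseFit]) -> pd.DataFrame:
    selected = compare_families(list(fits))
    rows = [
        {
            "family": f.family,
            "aic": f.aic,
            "mse": f.mse,
            "n_bins": f.n_bins,
            "selected": f is selected,
            "flags": ";".join(f.flags),
        }
        for f in fits
    ]
    return pd.DataFrame(rows)


def peak_temperature(fit: ResponseFit) -> float:
    """Vertex of the quadratic response, -b2/(2*b3); needs b3 < 0."""
    if fit.family != "polynomial":
        raise FitError(f"peak temperature needs a polynomial fit, got {fit.family}")
    b2 = fit.coefficients["b2"]
    b3 = fit.coefficients["b3"]
    if b3 >= 0:
        raise FitError(
            "no interior peak: b3 >= 0 (volume does not decline at high SST)"
        )
    return float(-b2 / (2.0 * b3))
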