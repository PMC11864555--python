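"""Mixed-effects model comparison for migration timing and residence time.

Three candidate structures are fit to per region-year phenology records and
compared by AIC (lowest wins):

1. ``response ~ regime`` — regional timing identical, regime shifts common;
2. ``response ~ regime + (1 | region)`` — a random region intercept: regions
   differ in level, regime shifts are common to all;
3. ``response ~ regime * region`` — fully regional regime effects (ordinary
   least squares; the full interaction leaves no random term).

All likelihoods are maximum likelihood, not REML: AIC comparisons span
different fixed-effect structures, and REML likelihoods are not comparable
across those.  The parameter count k includes every estimated parameter —
fixed effects, the random-intercept variance (structure 2), and the residual
variance — so aic = 2k - 2*logLik exactly.

Contrast p-values are Wald tests against a t reference with n - k_fixed
degrees of freedom.  The reference levels are T1 and the alphabetically
first region (CR1 in the default registry).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ComparabilityError, DesignError, FitError

RESPONSES = ("coastal_mdmt", "riverine_mdmt", "residence_days")


@dataclass(frozen=True)
class ModelStructure:
    """One candidate model structure (see module docstring)."""

    id: int
    fixed: str
    random: Optional[str]


STRUCTURES: dict[int, ModelStructure] = {
    1: ModelStructure(1, "regime", None),
    2: ModelStructure(2, "regime", "region intercept"),
    3: ModelStructure(3, "regime * region", None),
}


def significance_tier(p: float) -> tuple[str, str]:
    """(marker, tier) for a p-value, using the study's marker convention.

    The marker-to-threshold mapping ('*' for p < 0.01, '**' for p < 0.05,
    '***' for p < 0.001) inverts the usual convention for '*' and '**'; it is
    reproduced verbatim, and the numeric p-value should always be reported
    alongside.  p < 0.1 is tiered "marginal" with no marker.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***", "p<0.001"
    if p < 0.01:
        return "*", "p<0.01"
    if p < 0.05:
        return "**", "p<0.05"
    if p < 0.1:
        return "", "marginal"
    return "", "ns"


@dataclass
class ModelFit:
    """A fitted candidate structure with its AIC bookkeeping and contrasts."""

    structure_id: int
    response: str
    formula: str
    coef_table: pd.DataFrame          # term, estimate, se, p, marker
    contrasts: pd.DataFrame           # contrast, estimate, se, p, marker
    log_likelihood: float
    k: int                            # all estimated parameters incl. variances
    k_fixed: int
    aic: float
    n_obs: int
    resid_var: float
    random_intercept_var: Optional[float]
    data_signature: str
    converged: bool = True

    @property
    def structure(self) -> ModelStructure:
        return STRUCTURES[self.structure_id]


def _signature(records: pd.DataFrame, response: str) -> str:
    cols = ["region", "regime", response]
    body = records[cols].sort_values(cols).to_csv(index=False)
    return hashlib.md5((response + "\n" + body).encode()).hexdigest()


def _wald(est: float, se: float, df: int) -> float:
    # degenerate-variance guard: zero/invalid se means either "no evidence of
    # any difference" (est ~ 0) or an exactly reproduced difference (p -> 0)
    if not np.isfinite(se) or se <= 0.0:
        return 1.0 if abs(est) < 1e-8 else 0.0
    t = est / se
    if not np.isfinite(t):
        return 0.0
    return float(2.0 * stats.t.sf(abs(t), df=max(df, 1)))


def _contrast_rows(
    design_info,
    params: np.ndarray,
    cov: np.ndarray,
    df: int,
    pairs: list[tuple[str, dict, dict]],
) -> pd.DataFrame:
    """Wald contrasts from design-row differences.

    ``pairs`` holds (name, cell_a, cell_b) factor-level dicts; the contrast is
    mean(cell_a) - mean(cell_b).
    """
    rows = []
    for name, cell_a, cell_b in pairs:
        ra = np.asarray(
            build_design_matrices([design_info], pd.DataFrame({k: [v] for k, v in cell_a.items()}))[0]
        )[0]
        rb = np.asarray(
            build_design_matrices([design_info], pd.DataFrame({k: [v] for k, v in cell_b.items()}))[0]
        )[0]
        L = ra - rb
        est = float(L @ params)
        var = float(L @ cov @ L)
        se = float(np.sqrt(max(var, 0.0)))
        p = _wald(est, se, df)
        marker, tier = significance_tier(p)
        rows.append(
            {"contrast": name, "estimate": est, "se": se, "p": p,
             "marker": marker, "tier": tier}
        )
    return pd.DataFrame(rows, columns=["contrast", "estimate", "se", "p", "marker", "tier"])


def _reference(levels: Sequence[str], preferred: str) -> str:
    levels = sorted(levels)
    return preferred if preferred in levels else levels[0]


def fit_lme(
    records: pd.DataFrame,
    structure: int | ModelStructure,
    response: str = "coastal_mdmt",
) -> ModelFit:
    """Fit one candidate structure by maximum likelihood.

    ``records`` needs columns (region, regime, <response>); incomplete rows
    are dropped.  Raises DesignError when a regime (or, for structure 3, a
    regime-region cell) has no records, FitError on non-convergence.
    """
    sid = structure.id if isinstance(structure, ModelStructure) else int(structure)
    if sid not in STRUCTURES:
        raise DesignError(f"unknown model structure {sid}")
    data = records.dropna(subset=["region", "regime", response]).copy()
    data["region"] = data["region"].astype(str)
    data["regime"] = data["regime"].astype(str)
    regimes = sorted(data["regime"].unique())
    regions = sorted(data["region"].unique())
    if len(regimes) < 2:
        raise DesignError(f"need >=2 regimes with records, have {regimes}")
    if sid == 2 and len(regions) < 2:
        raise DesignError("structure 2 needs >=2 regions for a random intercept")
    if sid == 3:
        cells = data.groupby(["regime", "region"]).size()
        want = len(regimes) * len(regions)
        if len(cells) < want:
            have = set(cells.index)
            missing = [
                (g, r) for g in regimes for r in regions if (g, r) not in have
            ]
            raise DesignError(f"empty regime-region cells for structure 3: {missing}")

    ref_regime = _reference(regimes, "T1")
    ref_region = regions[0]
    regime_term = f"C(regime, Treatment(reference='{ref_regime}'))"
    region_term = f"C(region, Treatment(reference='{ref_region}'))"
    if sid in (1, 2):
        formula = f"{response} ~ {regime_term}"
    else:
        formula = f"{response} ~ {regime_term} * {region_term}"

    n = len(data)
    random_var: Optional[float] = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if sid == 2:
                # boundary fit (sigma_b^2 = 0): the marginal likelihood
                # collapses to plain OLS on the same fixed effects
                ols_model = smf.ols(formula, data=data)
                ols_res = ols_model.fit()
                boundary_llf = float(ols_res.llf)
                try:
                    model = smf.mixedlm(formula, data=data, groups=data["region"])
                    res = model.fit(reml=False)
                    converged = bool(getattr(res, "converged", True))
                    mixed_ok = np.isfinite(res.llf)
                except (np.linalg.LinAlgError, ValueError):
                    # singular Hessian at the variance boundary
                    mixed_ok = False
                if mixed_ok and float(res.llf) >= boundary_llf - 1e-10:
                    fe = res.fe_params
                    names = list(fe.index)
                    cov_all = res.cov_params()
                    cov = cov_all.loc[names, names].to_numpy()
                    params = fe.to_numpy()
                    bse = np.sqrt(np.diag(cov))
                    llf = float(res.llf)
                    random_var = float(res.cov_re.iloc[0, 0])
                    resid_var = float(res.scale)
                else:
                    model = ols_model
                    converged = True
                    names = list(ols_res.params.index)
                    params = ols_res.params.to_numpy()
                    cov = np.asarray(ols_res.cov_params())
                    bse = ols_res.bse.to_numpy()
                    llf = boundary_llf
                    random_var = 0.0
                    resid_var = float(ols_res.ssr) / n
                k_fixed = len(names)
                k = k_fixed + 2  # + random-intercept variance + residual variance
            else:
                model = smf.ols(formula, data=data)
                res = model.fit()
                converged = True
                names = list(res.params.index)
                params = res.params.to_numpy()
                cov = np.asarray(res.cov_params())
                bse = res.bse.to_numpy()
                llf = float(res.llf)  # OLS llf is the ML Gaussian log-likelihood
                rss = float(res.ssr)
                resid_var = rss / n
                k_fixed = len(names)
                k = k_fixed + 1  # + residual variance
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise FitError(f"structure {sid} fit failed: {exc}") from exc

    aic = 2.0 * k - 2.0 * llf
    design_info = model.data.design_info
    df_resid = n - k_fixed

    coef_rows = []
    for name, est, se in zip(names, params, bse):
        p = _wald(float(est), float(se), df_resid)
        marker, tier = significance_tier(p)
        coef_rows.append(
            {"term": name, "estimate": float(est), "se": float(se), "p": p,
             "marker": marker, "tier": tier}
        )
    coef_table = pd.DataFrame(coef_rows)

    pairs: list[tuple[str, dict, dict]] = []
    regime_pairs = [
        (b, a) for i, a in enumerate(regimes) for b in regimes[i + 1:]
    ]
    if sid in (1, 2):
        for b, a in regime_pairs:
            pairs.append((f"{b}-{a}", {"regime": b}, {"regime": a}))
    else:
        # regime differences within each region (Fig-5-style) ...
        for r in regions:
            for b, a in regime_pairs:
                pairs.append(
                    (f"{b}-{a}|{r}", {"regime": b, "region": r}, {"regime": a, "region": r})
                )
        # ... and region differences vs the reference region within each regime
        for g in regimes:
            for r in regions:
                if r == ref_region:
                    continue
                pairs.append(
                    (f"{r}-{ref_region}|{g}",
                     {"regime": g, "region": r}, {"regime": g, "region": ref_region})
                )
    contrasts = _contrast_rows(design_info, params, cov, df_resid, pairs)

    return ModelFit(
        structure_id=sid,
        response=response,
        formula=formula,
        coef_table=coef_table,
        contrasts=contrasts,
        log_likelihood=llf,
        k=k,
        k_fixed=k_fixed,
        aic=float(aic),
        n_obs=n,
        resid_var=resid_var,
        random_intercept_var=random_var,
        data_signature=_signature(data, response),
        converged=converged,
    )


def select_structure(fits: Sequence[ModelFit]) -> ModelFit:
    """Lowest-AIC fit; ties broken by smaller k, then lower structure id.

    All fits must be on identical records and the same response.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ComparabilityError("need >=2 fits to select a structure")
    sig = {(f.response, f.data_signature, f.n_obs) for f in fits}
    if len(sig) != 1:
        raise ComparabilityError("fits were computed on differing record sets")
    return min(fits, key=lambda f: (f.aic, f.k, f.structure_id))


def comparison_table(fits: Sequence[ModelFit], selected: ModelFit | None = None) -> pd.DataFrame:
    """AIC comparison table in the layout of the study's model table."""
    if selected is None:
        selected = select_structure(fits)
    rows = [
        {
            "structure": f.structure_id,
            "fixed": f.structure.fixed,
            "random": f.structure.random or "",
            "log_likelihood": f.log_likelihood,
            "k": f.k,
            "aic": f.aic,
            "selected": f is selected,
        }
        for f in sorted(fits, key=lambda f: f.structure_id)
    ]
    return pd.DataFrame(rows)


class MixedModelSelector(BaseEstimator):
    """AIC-based selection among the three candidate structures.

    fit() fits every requested structure to a phenology-record table and
    stores the per-structure fits, the comparison table and the winner.
    """

    def __init__(self, response: str = "coastal_mdmt", structures: Sequence[int] = (1, 2, 3)):
        self.response = response
        self.structures = structures

    def fit(self, records: pd.DataFrame):
        self.fits_ = [fit_lme(records, sid, response=self.response) for sid in self.structures]
        self.selected_ = select_structure(self.fits_)
        self.comparison_ = comparison_table(self.fits_, self.selected_)
        return self

    @property
    def selected_structure_(self) -> int:
        return self.selected_.structure_id
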