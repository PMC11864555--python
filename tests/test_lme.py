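"""Mixed-model fitting, AIC accounting, selection and significance tiers."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from chumrun.errors import ComparabilityError, DesignError
from chumrun.lme import (
    MixedModelSelector,
    ModelFit,
    fit_lme,
    select_structure,
    significance_tier,
)
from chumrun.simulate import simulate_lme_records


def balanced_records(means={"T1": 40.0, "T2": 36.0, "T3": 40.0}, n_regions=4, n_years=4):
    rows = []
    for i in range(n_regions):
        for regime, mean in means.items():
            for y in range(n_years):
                rows.append(
                    {"region": f"CR{i+1}", "regime": regime, "year": 2006 + y, "y": mean}
                )
    return pd.DataFrame(rows)


class TestFitLme:
    def test_noise_free_balanced_contrast_equals_group_difference(self):
        fit = fit_lme(balanced_records(), 1, response="y")
        c = fit.contrasts.set_index("contrast")
        assert c.loc["T2-T1", "estimate"] == pytest.approx(-4.0, abs=1e-10)
        assert c.loc["T3-T1", "estimate"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_response_degenerate_variance_handled(self):
        records = balanced_records(means={"T1": 5.0, "T2": 5.0, "T3": 5.0})
        for structure in (1, 2):
            fit = fit_lme(records, structure, response="y")
            assert np.allclose(fit.contrasts["estimate"], 0.0, atol=1e-9)
            assert fit.coef_table.loc[0, "estimate"] == pytest.approx(5.0)

    def test_missing_regime_is_design_error(self):
        records = balanced_records()
        with pytest.raises(DesignError):
            fit_lme(records[records.regime == "T1"], 1, response="y")

    def test_empty_cell_rejected_for_structure3(self):
        records = balanced_records()
        trimmed = records[~((records.regime == "T2") & (records.region == "CR2"))]
        with pytest.raises(DesignError, match="cell"):
            fit_lme(trimmed, 3, response="y")

    def test_aic_identity_all_structures(self, noisy_phenology):
        *_, phen = noisy_phenology
        for response in ("coastal_mdmt", "residence_days"):
            for structure in (1, 2, 3):
                fit = fit_lme(phen, structure, response=response)
                assert fit.aic == pytest.approx(
                    2 * fit.k - 2 * fit.log_likelihood, abs=1e-8
                )
                assert fit.n_obs == len(phen)

    def test_zero_region_variance_boundary_matches_fixed_model(self):
        """With no region effect in the data, adding the random intercept
        must change the ML log-likelihood by < 1e-4."""
        rec = simulate_lme_records(region_sd=0.0, resid_sd=2.0, seed=3).rename(
            columns={"response": "y"}
        )
        f1 = fit_lme(rec, 1, response="y")
        f2 = fit_lme(rec, 2, response="y")
        assert abs(f2.log_likelihood - f1.log_likelihood) < 1e-4

    def test_t2_contrast_estimator_consistency(self):
        """Estimate spread shrinks as pooled years grow (n = 5, 20, 80)."""
        spreads = []
        for n_years in (5, 20, 80):
            seq = tuple(np.tile(["T1", "T2", "T3"], n_years)[:n_years * 3])
            estimates = []
            for rep in range(15):
                rec = simulate_lme_records(
                    regime_sequence=seq, region_sd=2.7, resid_sd=2.0,
                    seed=rep + n_years,
                ).rename(columns={"response": "y"})
                fit = fit_lme(rec, 2, response="y")
                c = fit.contrasts.set_index("contrast")
                estimates.append(c.loc["T2-T1", "estimate"])
            spreads.append(np.std(estimates))
            assert abs(np.mean(estimates) - (-4.0)) < 3.0 * np.std(estimates) / np.sqrt(15) + 0.2
        assert spreads[2] < spreads[0]


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript + lme4")
def test_loglik_matches_lme4_reference(tmp_path):
    """Independent oracle: ML log-likelihoods of all three structures agree
    with R's lm/lmer on the same records to 1e-4."""
    rec = simulate_lme_records(region_sd=2.7, resid_sd=1.5, seed=7).rename(
        columns={"response": "y"}
    )
    csv = tmp_path / "rec.csv"
    rec.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m1 <- lm(y ~ regime, data=d)
        m2 <- lmer(y ~ regime + (1|region), data=d, REML=FALSE)
        m3 <- lm(y ~ regime * region, data=d)
        cat(sprintf("%.10f\\n", c(logLik(m1), logLik(m2), logLik(m3))))
        """
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    reference = [float(v) for v in out.stdout.split()]
    ours = [fit_lme(rec, s, response="y").log_likelihood for s in (1, 2, 3)]
    assert ours == pytest.approx(reference, abs=1e-4)


def _stub_fit(structure_id, aic, k, sig="s", response="y", n_obs=78):
    return ModelFit(
        structure_id=structure_id, response=response, formula="",
        coef_table=pd.DataFrame(), contrasts=pd.DataFrame(),
        log_likelihood=(2 * k - aic) / 2.0, k=k, k_fixed=k - 1, aic=aic,
        n_obs=n_obs, resid_var=1.0, random_intercept_var=None,
        data_signature=sig,
    )


class TestSelectStructure:
    def test_published_coastal_aics_select_structure_2(self):
        fits = [
            _stub_fit(1, 439.87, 4),
            _stub_fit(2, 426.98, 5),
            _stub_fit(3, 431.68, 19),
        ]
        assert select_structure(fits).structure_id == 2

    def test_published_riverine_aics_select_structure_3(self):
        fits = [
            _stub_fit(1, 237.17, 4),
            _stub_fit(2, 236.39, 5),
            _stub_fit(3, 233.75, 19),
        ]
        assert select_structure(fits).structure_id == 3

    def test_aic_tie_breaks_to_smaller_k_then_lower_id(self):
        assert select_structure(
            [_stub_fit(3, 100.0, 6), _stub_fit(2, 100.0, 4)]
        ).structure_id == 2
        assert select_structure(
            [_stub_fit(3, 100.0, 4), _stub_fit(1, 100.0, 4)]
        ).structure_id == 1

    def test_differing_record_sets_rejected(self):
        with pytest.raises(ComparabilityError):
            select_structure([_stub_fit(1, 10.0, 4, sig="a"), _stub_fit(2, 9.0, 5, sig="b")])


class TestSignificanceTier:
    @pytest.mark.parametrize(
        "p,marker,tier",
        [
            (0.0005, "***", "p<0.001"),
            (0.005, "*", "p<0.01"),
            (0.03, "**", "p<0.05"),
            (0.07, "", "marginal"),
            (0.5, "", "ns"),
        ],
    )
    def test_markers_follow_study_convention(self, p, marker, tier):
        assert significance_tier(p) == (marker, tier)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_tier(1.5)


class TestSelector:
    def test_selector_fits_all_and_flags_one_winner(self, noisy_phenology):
        *_, phen = noisy_phenology
        sel = MixedModelSelector(response="coastal_mdmt").fit(phen)
        assert len(sel.fits_) == 3
        assert sel.comparison_["selected"].sum() == 1
        assert sel.selected_structure_ in (1, 2, 3)
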