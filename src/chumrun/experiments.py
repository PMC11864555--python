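"""Parameter-recovery experiments on synthetic data.

The study's raw catch and reanalysis SST are not publicly deposited, so the
package validates itself by recovery: simulate data whose regime structure,
injected effects and phenology are known exactly, run the full analysis, and
measure how well each quantity is recovered.  These experiment drivers are
shared by the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FitError
from .lme import MixedModelSelector, fit_lme
from .phenology import binned_volumes, phenology_table
from .regimes import label_years
from .simulate import (
    Scenario,
    make_scenario_preset,
    simulate_dataset,
    simulate_lme_records,
    sst_at_day,
)
from .thermal import FAMILIES, compare_families, fit_response, peak_temperature


def _split(data: pd.DataFrame, location: str) -> pd.DataFrame:
    return data[data["location"] == location]


def _phenology_from_scenario(scenario: Scenario):
    ds = simulate_dataset(scenario)
    _, labels = label_years(_split(ds.data, "sst"))
    phen = phenology_table(_split(ds.data, "coast"), _split(ds.data, "river"), labels)
    return ds, labels, phen


def noise_free_identity(seed: int = 0) -> dict:
    """All noise off: labels, MDMTs and residences must equal truth exactly."""
    scenario = make_scenario_preset("mixed-13yr", seed=seed).without_noise()
    ds, labels, phen = _phenology_from_scenario(scenario)
    label_map = dict(zip(labels["year"].astype(int), labels["label"]))
    label_hits = sum(
        label_map.get(int(y)) == v for y, v in ds.truth["regimes"].items()
    )
    exact = {"coastal_mdmt": 0, "riverine_mdmt": 0, "residence_days": 0}
    for row in phen.itertuples():
        for key in exact:
            exact[key] += getattr(row, key) == ds.truth[key][row.region][str(row.year)]
    n = len(phen)
    return {
        "n_years": len(ds.truth["regimes"]),
        "label_accuracy": label_hits / len(ds.truth["regimes"]),
        "n_records": n,
        "mdmt_exact_fraction": exact["coastal_mdmt"] / n,
        "riverine_exact_fraction": exact["riverine_mdmt"] / n,
        "residence_exact_fraction": exact["residence_days"] / n,
    }


def classification_robustness(n_datasets: int = 16, seed: int = 0) -> dict:
    """Label accuracy under the default 0.3 °C SST noise.

    Each replicate dataset contributes 13 year-labels (16 x 13 = 208 years).
    """
    hits = total = 0
    for rep in range(n_datasets):
        scenario = make_scenario_preset("mixed-13yr", seed=seed + rep)
        ds = simulate_dataset(scenario)
        _, labels = label_years(_split(ds.data, "sst"))
        label_map = dict(zip(labels["year"].astype(int), labels["label"]))
        for y, truth_label in ds.truth["regimes"].items():
            total += 1
            hits += label_map.get(int(y)) == truth_label
    return {"n_years": total, "accuracy": hits / total}


def structure_recovery(
    n_replicates: int = 100,
    region_sd: float = 2.7,
    resid_sd: float = 1.5,
    seed: int = 0,
) -> dict:
    """AIC structure selection on records simulated under structures 2 and 1."""
    picks_s2 = []
    picks_s1 = []
    for rep in range(n_replicates):
        rec = simulate_lme_records(
            region_sd=region_sd, resid_sd=resid_sd, seed=seed + rep
        ).rename(columns={"response": "y"})
        picks_s2.append(MixedModelSelector(response="y").fit(rec).selected_structure_)
        rec1 = simulate_lme_records(
            region_sd=0.0, resid_sd=resid_sd, seed=100_000 + seed + rep
        ).rename(columns={"response": "y"})
        picks_s1.append(MixedModelSelector(response="y").fit(rec1).selected_structure_)
    picks_s2 = np.array(picks_s2)
    picks_s1 = np.array(picks_s1)
    return {
        "n_replicates": n_replicates,
        "structure2_rate_under_s2": float((picks_s2 == 2).mean()),
        "structure3_rate_under_s2": float((picks_s2 == 3).mean()),
        "structure1_rate_under_s1": float((picks_s1 == 1).mean()),
        "structure3_rate_under_s1": float((picks_s1 == 3).mean()),
    }


def t2_effect_recovery(n_replicates: int = 500, seed: int = 0) -> dict:
    """Recover the injected T2 coastal-arrival advance through the pipeline.

    Each replicate simulates a mixed-13yr dataset with full catch noise,
    recomputes labels and MDMTs, fits the random-intercept structure and
    takes the T2-vs-T1 contrast on coastal MDMT (truth: -t2_arrival_advance).
    """
    estimates = []
    for rep in range(n_replicates):
        scenario = make_scenario_preset("mixed-13yr", seed=seed + rep)
        _, _, phen = _phenology_from_scenario(scenario)
        fit = fit_lme(phen, 2, response="coastal_mdmt")
        c = fit.contrasts
        estimates.append(
            float(c.loc[c["contrast"] == "T2-T1", "estimate"].iloc[0])
        )
    estimates = np.asarray(estimates)
    return {
        "n_replicates": n_replicates,
        "injected_days": -4.0,
        "mean_estimate": float(estimates.mean()),
        "sd_estimate": float(estimates.std(ddof=1)),
    }


def thermal_recovery(
    n_replicates: int = 50,
    north_region: str = "CR2",
    south_region: str = "CR5",
    seed: int = 0,
) -> dict:
    """Family selection and quadratic-peak recovery at known pulse SSTs.

    The shift-free thermal-response preset centers coastal pulses where the
    mean cooling curve reads ~18.5 °C (north) and ~20.5 °C (south); each
    replicate fits all families to one northern and one southern region's
    pooled coastal bins (2 x n_replicates fits in total).
    """
    poly_wins = 0
    n_fits = 0
    peaks: dict[str, list[float]] = {"north": [], "south": []}
    truths: dict[str, list[float]] = {"north": [], "south": []}
    for rep in range(n_replicates):
        scenario = make_scenario_preset("thermal-response", seed=seed + rep)
        ds = simulate_dataset(scenario)
        labels = pd.DataFrame(
            {"year": scenario.years, "label": list(scenario.regime_sequence)}
        )
        for area, region in (("north", north_region), ("south", south_region)):
            catch = ds.data[
                (ds.data["location"] == "coast") & (ds.data["region"] == region)
            ]
            sst = ds.data[
                (ds.data["location"] == "sst") & (ds.data["region"] == region)
            ]
            bins = binned_volumes(catch, sst, labels)
            fits = []
            for family in FAMILIES:
                try:
                    fits.append(fit_response(bins, family))
                except FitError:
                    continue
            n_fits += 1
            poly_wins += compare_families(fits).family == "polynomial"
            poly = next(f for f in fits if f.family == "polynomial")
            center = scenario.coastal_pulse_center(region, scenario.start_year)
            truths[area].append(
                sst_at_day(scenario, region, scenario.start_year, center)
            )
            peaks[area].append(peak_temperature(poly))
    return {
        "n_fits": n_fits,
        "polynomial_selection_rate": poly_wins / n_fits,
        "peak_north": float(np.mean(peaks["north"])),
        "truth_north": float(np.mean(truths["north"])),
        "peak_south": float(np.mean(peaks["south"])),
        "truth_south": float(np.mean(truths["south"])),
    }


def regional_mdmt_spread(seed: int = 0) -> dict:
    """Between-region spread (sd over region means) of coastal MDMT."""
    scenario = make_scenario_preset("mixed-13yr", seed=seed)
    _, _, phen = _phenology_from_scenario(scenario)
    region_means = phen.groupby("region")["coastal_mdmt"].mean()
    return {
        "n_regions": len(region_means),
        "sd_days": float(region_means.std(ddof=0)),
    }
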