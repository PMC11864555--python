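"""Synthetic daily SST and Chum catch series with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes:

* Autumn SST in each region follows a smooth logistic-in-time cooling ramp
  from ``sst_start`` to ``sst_end`` over the 92-day Oct-Dec window, plus
  i.i.d. Gaussian daily noise.  The day the mean curve first drops below the
  20 °C migration threshold is placed analytically, so the true crossing day
  is known exactly.  Regime shifts move that crossing: T1 years cool
  ``early_shift`` days early everywhere, T3 years ``late_shift`` days late
  everywhere, and in T2 years the north cools early while the south is
  delayed by ``ns_offset`` days.

* Coastal arrival is a bell-shaped catch pulse whose center sits
  ``arrival_lag`` days after the *climatological* crossing day, advanced by
  ``t2_arrival_advance`` days in T2 years (the injected effect the mixed
  models must recover); overall cooling timing (T1 vs T3) does not move the
  pulse.  Daily counts are Poisson draws around the pulse intensity.

* Riverine entry is the coastal pulse shifted by a per-region coastal
  residence time and binomially thinned, so no fish is created in the river.

Every region-year draws from its own RNG substream derived from
``(seed, region, year)``, so adding regions or years never perturbs existing
series, and fixing the seed fixes the whole dataset bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ScenarioError, ValidationError
from .regions import WINDOW_LENGTH, AnalysisWindow, Region, default_registry

REGIMES = ("T1", "T2", "T3")

#: climatological first-sub-20 °C day per region (days since Oct 1);
#: north cools ~8 days before the south, between-region MDMT sd ≈ 2.7 d.
DEFAULT_BASE_CROSS_DAY = {
    "CR1": 25, "CR2": 28, "CR3": 31, "CR4": 33, "CR5": 36, "CR6": 40,
}

#: days between coastal MDMT and riverine MDMT; longest in the far north,
#: shortest in the south (southern fish enter rivers soon after arrival).
DEFAULT_RESIDENCE_MEAN = {
    "CR1": 25, "CR2": 15, "CR3": 12, "CR4": 10, "CR5": 8, "CR6": 7,
}


def lag_for_target_sst(
    target: float,
    sst_start: float = 24.0,
    sst_end: float = 12.0,
    threshold: float = 20.0,
    ramp_scale: float = 10.0,
) -> float:
    """Days after the threshold crossing at which the mean ramp equals ``target``.

    Negative if ``target`` lies above the threshold (arrival before cooling).
    Used to place arrival pulses at a prescribed water temperature.
    """
    if not (sst_end < target < sst_start):
        raise ScenarioError(f"target SST {target} outside ramp ({sst_end}, {sst_start})")
    r_thr = (sst_start - threshold) / (threshold - sst_end)
    r_tgt = (sst_start - target) / (target - sst_end)
    return ramp_scale * (math.log(r_tgt) - math.log(r_thr))


@dataclass
class Scenario:
    """Parameter bundle for one synthetic study.

    Day-valued parameters are in days since Oct 1 (window days 0..91).
    ``base_cross_day``, ``arrival_lag`` and ``residence_mean`` accept either a
    scalar (broadcast to all regions) or a per-region mapping.
    """

    regime_sequence: Sequence[str]
    start_year: int = 2006
    base_cross_day: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_BASE_CROSS_DAY)
    )
    early_shift: float = 10.0
    late_shift: float = 10.0
    ns_offset: float = 8.0
    sst_start: float = 24.0
    sst_end: float = 12.0
    sst_noise_sd: float = 0.3
    ramp_scale: float = 10.0
    threshold: float = 20.0
    run_size: float = 1000.0
    arrival_lag: Mapping[str, float] | float | None = None
    pulse_sd: float = 4.0
    residence_mean: Mapping[str, int] | int = field(
        default_factory=lambda: dict(DEFAULT_RESIDENCE_MEAN)
    )
    t2_arrival_advance: float = 4.0
    arrival_noise_sd: float = 3.5
    residence_noise_sd: float = 2.0
    river_return_rate: float = 0.8
    poisson_noise: bool = True
    seed: int = 0
    regions: Sequence[Region] = field(default_factory=default_registry)

    @property
    def n_years(self) -> int:
        return len(self.regime_sequence)

    @property
    def years(self) -> list[int]:
        return [self.start_year + i for i in range(self.n_years)]

    def __post_init__(self) -> None:
        if not (self.sst_start > self.threshold > self.sst_end):
            raise ScenarioError(
                "need sst_start > threshold > sst_end so a crossing always exists"
            )
        if self.arrival_lag is None:
            # place arrival pulses where the observed thermal-response curves
            # peak: ~18.5 °C in the north, ~20.5 °C in the south
            north = lag_for_target_sst(
                18.5, self.sst_start, self.sst_end, self.threshold, self.ramp_scale
            )
            south = lag_for_target_sst(
                20.5, self.sst_start, self.sst_end, self.threshold, self.ramp_scale
            )
            self.arrival_lag = {
                r.id: (north if r.area == "north" else south) for r in self.regions
            }
        self.validate()

    # -- parameter resolution -------------------------------------------------

    def _per_region(self, value, name: str) -> dict[str, float]:
        ids = [r.id for r in self.regions]
        if isinstance(value, Mapping):
            missing = [i for i in ids if i not in value]
            if missing:
                raise ScenarioError(f"{name} missing regions {missing}")
            return {i: value[i] for i in ids}
        return {i: value for i in ids}

    def base_cross(self, region_id: str) -> float:
        return self._per_region(self.base_cross_day, "base_cross_day")[region_id]

    def lag(self, region_id: str) -> float:
        return self._per_region(self.arrival_lag, "arrival_lag")[region_id]

    def residence(self, region_id: str) -> int:
        return int(self._per_region(self.residence_mean, "residence_mean")[region_id])

    def region(self, region_id: str) -> Region:
        for r in self.regions:
            if r.id == region_id:
                return r
        raise ScenarioError(f"unknown region {region_id!r}")

    def regime_of(self, year: int) -> str:
        idx = year - self.start_year
        if not 0 <= idx < self.n_years:
            raise ScenarioError(f"year {year} outside scenario {self.years[0]}..{self.years[-1]}")
        return self.regime_sequence[idx]

    def validate(self) -> None:
        for regime in self.regime_sequence:
            if regime not in REGIMES:
                raise ScenarioError(f"unknown regime label {regime!r}")
        if not (self.sst_start > self.threshold > self.sst_end):
            raise ScenarioError(
                "need sst_start > threshold > sst_end so a crossing always exists"
            )
        if self.run_size <= 0:
            raise ScenarioError("run_size must be > 0")
        if self.pulse_sd < 0:
            raise ScenarioError("pulse_sd must be >= 0")
        if not 0.0 < self.river_return_rate <= 1.0:
            raise ScenarioError("river_return_rate must be in (0, 1]")
        for rid in (r.id for r in self.regions):
            for year in self.years:
                regime = self.regime_of(year)
                cross = self.cross_day(rid, year)
                if not 0 <= cross <= WINDOW_LENGTH - 1:
                    raise ScenarioError(
                        f"crossing day {cross} for {rid}/{year} ({regime}) outside window"
                    )
                c = self.coastal_pulse_center(rid, year)
                r = c + self.residence(rid)
                if not (0 <= c <= WINDOW_LENGTH - 1 and 0 <= r <= WINDOW_LENGTH - 1):
                    raise ScenarioError(
                        f"pulse center outside window for {rid}/{year}: coastal {c}, riverine {r}"
                    )

    # -- ground truth ---------------------------------------------------------

    def regime_shift(self, region_id: str, regime: str) -> float:
        """Days the regime moves this region's crossing versus climatology."""
        area = self.region(region_id).area
        if regime == "T1":
            return -self.early_shift
        if regime == "T3":
            return self.late_shift
        if regime == "T2":
            return -self.early_shift if area == "north" else self.ns_offset
        raise ScenarioError(f"unknown regime label {regime!r}")

    def cross_day(self, region_id: str, year: int) -> int:
        """True first-sub-threshold day of the noise-free series."""
        shift = self.regime_shift(region_id, self.regime_of(year))
        return int(round(self.base_cross(region_id) + shift))

    def coastal_pulse_center(self, region_id: str, year: int) -> int:
        """True coastal MDMT before arrival jitter (integer day)."""
        regime = self.regime_of(year)
        advance = self.t2_arrival_advance if regime == "T2" else 0.0
        return int(round(self.base_cross(region_id) + self.lag(region_id) - advance))

    # -- RNG + noise control --------------------------------------------------

    def rng(self, region_id: str, year: int, stream: int) -> np.random.Generator:
        """Independent substream for one region-year (0 = SST, 1 = catch)."""
        ids = [r.id for r in self.regions]
        key = (ids.index(region_id), year, stream)
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))

    def without_noise(self) -> "Scenario":
        """Copy with all stochastic components disabled (exact-identity mode)."""
        return dataclasses.replace(
            self,
            sst_noise_sd=0.0,
            arrival_noise_sd=0.0,
            residence_noise_sd=0.0,
            poisson_noise=False,
        )

    def with_seed(self, seed: int) -> "Scenario":
        return dataclasses.replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# presets


#: regime of each year 2006-2018 (3 x T1, 5 x T2, 5 x T3)
MIXED_13YR_SEQUENCE = (
    "T1", "T3", "T1", "T2", "T3", "T2", "T3", "T2", "T3", "T2", "T2", "T3", "T1",
)

PRESET_NAMES = ("T1-like", "T2-like", "T3-like", "mixed-13yr", "thermal-response")


def make_scenario_preset(name: str, seed: int = 0) -> Scenario:
    """Fully parameterized scenario presets.

    ``mixed-13yr`` mirrors the 13-year study composition (3 T1, 5 T2, 5 T3
    years in the 2006-2018 order); ``T1-like``/``T2-like``/``T3-like`` repeat
    a single regime for 13 years; ``thermal-response`` is a shift-free
    scenario whose arrival pulses sit at 18.5 °C (north) / 20.5 °C (south),
    for thermal-response-curve recovery experiments.
    """
    if name == "mixed-13yr":
        return Scenario(regime_sequence=MIXED_13YR_SEQUENCE, seed=seed)
    if name in ("T1-like", "T2-like", "T3-like"):
        regime = name[:2]
        return Scenario(regime_sequence=(regime,) * 13, seed=seed)
    if name == "thermal-response":
        return Scenario(
            regime_sequence=("T1",) * 13,
            early_shift=0.0,
            late_shift=0.0,
            seed=seed,
        )
    raise ScenarioError(f"unknown preset {name!r}; know {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# simulation


def _mean_ramp(scenario: Scenario, cross_day: int) -> np.ndarray:
    """Noise-free daily SST with first sub-threshold value on ``cross_day``.

    The logistic ramp is time-shifted so the continuous 20 °C crossing falls
    at ``cross_day - 0.5``: the mean is above threshold on ``cross_day - 1``
    and strictly below on ``cross_day``.
    """
    s = scenario.ramp_scale
    span = scenario.sst_start - scenario.sst_end
    r = (scenario.sst_start - scenario.threshold) / (scenario.threshold - scenario.sst_end)
    t0 = (cross_day - 0.5) - s * math.log(r)
    t = np.arange(WINDOW_LENGTH, dtype=float)
    return scenario.sst_end + span / (1.0 + np.exp((t - t0) / s))


def simulate_sst(scenario: Scenario, region_id: str, year: int) -> np.ndarray:
    """Daily SST (°C) for one region-year; deterministic given the seed."""
    mean = _mean_ramp(scenario, scenario.cross_day(region_id, year))
    if scenario.sst_noise_sd > 0:
        rng = scenario.rng(region_id, year, stream=0)
        return mean + rng.normal(0.0, scenario.sst_noise_sd, size=WINDOW_LENGTH)
    return mean


def sst_at_day(scenario: Scenario, region_id: str, year: int, day: float) -> float:
    """Mean-curve SST at a (possibly fractional) window day."""
    s = scenario.ramp_scale
    span = scenario.sst_start - scenario.sst_end
    r = (scenario.sst_start - scenario.threshold) / (scenario.threshold - scenario.sst_end)
    t0 = (scenario.cross_day(region_id, year) - 0.5) - s * math.log(r)
    return scenario.sst_end + span / (1.0 + math.exp((day - t0) / s))


def _pulse_intensity(center: int, sd: float, total: float) -> np.ndarray:
    """Bell-shaped expected daily counts over the window, mass ``total``."""
    days = np.arange(WINDOW_LENGTH, dtype=float)
    if sd <= 1e-9:
        pmf = np.zeros(WINDOW_LENGTH)
        pmf[center] = 1.0
    else:
        pmf = np.exp(-0.5 * ((days - center) / sd) ** 2)
        pmf /= pmf.sum()
    return total * pmf


def simulate_catch(
    scenario: Scenario, region_id: str, year: int
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Daily coastal and riverine catch counts for one region-year.

    Returns ``(coastal, riverine, truth)`` where truth records the realized
    pulse centers (true MDMTs) and residence time.  Riverine counts are the
    coastal counts shifted by the residence time and binomially thinned, so
    riverine total <= coastal total always holds.
    """
    rng = scenario.rng(region_id, year, stream=1)
    center = scenario.coastal_pulse_center(region_id, year)
    if scenario.arrival_noise_sd > 0:
        center += int(round(rng.normal(0.0, scenario.arrival_noise_sd)))
    center = int(np.clip(center, 0, WINDOW_LENGTH - 1))

    residence = scenario.residence(region_id)
    if scenario.residence_noise_sd > 0:
        residence += int(round(rng.normal(0.0, scenario.residence_noise_sd)))

    intensity = _pulse_intensity(center, scenario.pulse_sd, scenario.run_size)
    if scenario.poisson_noise:
        coastal = rng.poisson(intensity).astype(np.int64)
    else:
        coastal = np.rint(intensity).astype(np.int64)

    riverine = np.zeros(WINDOW_LENGTH, dtype=np.int64)
    shifted = np.roll(coastal, residence)
    if residence >= 0:
        shifted[:residence] = 0
    else:
        shifted[residence:] = 0
    if scenario.poisson_noise:
        riverine = rng.binomial(shifted, scenario.river_return_rate)
    else:
        riverine = np.rint(shifted * scenario.river_return_rate).astype(np.int64)

    truth = {
        "coastal_mdmt": center,
        "riverine_mdmt": center + residence,
        "residence_days": residence,
    }
    return coastal, riverine, truth


@dataclass
class SyntheticDataset:
    """Long-format synthetic data plus the generator's ground truth.

    ``data`` has columns (region, year, date, location, value) with location
    in {sst, coast, river}; ``truth`` is a nested dict keyed by region then
    year (string keys, JSON-friendly).
    """

    data: pd.DataFrame
    truth: dict

    def series(self, region_id: str, year: int, location: str) -> np.ndarray:
        sub = self.data[
            (self.data["region"] == region_id)
            & (self.data["year"] == year)
            & (self.data["location"] == location)
        ].sort_values("date")
        return sub["value"].to_numpy()

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(outdir / "data.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))

    @classmethod
    def read(cls, outdir: str | Path) -> "SyntheticDataset":
        outdir = Path(outdir)
        data = read_long_csv(outdir / "data.csv")
        truth = json.loads((outdir / "truth.json").read_text())
        return cls(data=data, truth=truth)


def read_long_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format (region, year, date, location, value) CSV."""
    df = pd.read_csv(path)
    required = {"region", "year", "date", "location", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["year"] = df["year"].astype(int)
    return df


def simulate_dataset(scenario: Scenario) -> SyntheticDataset:
    """Run the full generator: SST + coastal + riverine series for all
    region-years, with a complete truth record."""
    rows = []
    truth: dict = {
        "regimes": {str(y): scenario.regime_of(y) for y in scenario.years},
        "crossings": {},
        "coastal_mdmt": {},
        "riverine_mdmt": {},
        "residence_days": {},
    }
    for region in scenario.regions:
        rid = region.id
        for key in ("crossings", "coastal_mdmt", "riverine_mdmt", "residence_days"):
            truth[key][rid] = {}
        for year in scenario.years:
            window = AnalysisWindow(year)
            dates = [window.date_at(d).isoformat() for d in range(WINDOW_LENGTH)]
            sst = simulate_sst(scenario, rid, year)
            coastal, riverine, t = simulate_catch(scenario, rid, year)
            truth["crossings"][rid][str(year)] = scenario.cross_day(rid, year)
            truth["coastal_mdmt"][rid][str(year)] = t["coastal_mdmt"]
            truth["riverine_mdmt"][rid][str(year)] = t["riverine_mdmt"]
            truth["residence_days"][rid][str(year)] = t["residence_days"]
            for location, values in (("sst", sst), ("coast", coastal), ("river", riverine)):
                rows.append(
                    pd.DataFrame(
                        {
                            "region": rid,
                            "year": year,
                            "date": dates,
                            "location": location,
                            "value": values,
                        }
                    )
                )
    data = pd.concat(rows, ignore_index=True)
    data["date"] = pd.to_datetime(data["date"]).dt.date
    return SyntheticDataset(data=data, truth=truth)


def simulate_lme_records(
    regime_sequence: Sequence[str] = MIXED_13YR_SEQUENCE,
    region_ids: Sequence[str] | None = None,
    grand_mean: float = 33.5,
    regime_effects: Mapping[str, float] | None = None,
    region_sd: float = 2.7,
    resid_sd: float = 1.5,
    region_effects_random: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate phenology records directly at the mixed-model level.

    response_ij = grand_mean + regime_effect_j + b_i + e_ij with
    b_i ~ N(0, region_sd^2) (dropped when ``region_sd == 0``) and
    e_ij ~ N(0, resid_sd^2).  Used for model-structure recovery experiments
    where the data-generating structure must be controlled exactly.
    """
    if region_ids is None:
        region_ids = [r.id for r in default_registry()]
    if regime_effects is None:
        regime_effects = {"T1": 0.0, "T2": -4.0, "T3": 0.0}
    rng = np.random.default_rng(seed)
    intercepts = (
        rng.normal(0.0, region_sd, size=len(region_ids))
        if (region_effects_random and region_sd > 0)
        else np.zeros(len(region_ids))
    )
    rows = []
    for i, rid in enumerate(region_ids):
        for j, regime in enumerate(regime_sequence):
            value = (
                grand_mean
                + regime_effects[regime]
                + intercepts[i]
                + rng.normal(0.0, resid_sd)
            )
            rows.append(
                {"region": rid, "year": 2006 + j, "regime": regime, "response": value}
            )
    return pd.DataFrame(rows)
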