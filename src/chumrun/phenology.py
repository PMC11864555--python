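"""Migration-phenology statistics from daily catch series.

* MDMT (median date of migration timing): the first day on which the running
  cumulative catch strictly exceeds 50 % of the Oct-Dec total.  With an even
  total split exactly at 50 %, the next day wins ("more than 50 %" read
  strictly).
* Coastal residence time: riverine MDMT minus coastal MDMT (signed; negative
  values are retained but flagged).
* Temperature-binned migration volume: each day's catch accumulated into the
  1 °C bin containing that day's SST, pooled over the years of one regime and
  normalized to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataQualityError, UndefinedStatisticError


def mdmt(catch: np.ndarray | pd.Series) -> int:
    """First day index whose cumulative catch strictly exceeds half the total."""
    counts = np.asarray(catch, dtype=float)
    if counts.size == 0:
        raise UndefinedStatisticError("empty catch series")
    if (counts < 0).any():
        raise DataQualityError("negative catch counts")
    total = counts.sum()
    if total <= 0:
        raise UndefinedStatisticError("MDMT undefined: zero total catch in window")
    cumulative = np.cumsum(counts)
    return int(np.argmax(cumulative > 0.5 * total))


def residence_time(coastal_mdmt: int, riverine_mdmt: int) -> int:
    """Signed days between coastal arrival and river entry (riverine - coastal)."""
    if coastal_mdmt is None or riverine_mdmt is None:
        raise UndefinedStatisticError("residence time needs both MDMTs")
    return int(riverine_mdmt) - int(coastal_mdmt)


@dataclass(frozen=True)
class PhenologyRecord:
    region: str
    year: int
    regime: str
    coastal_mdmt: int
    riverine_mdmt: int
    residence_days: int

    @property
    def flagged(self) -> bool:
        """True when residence is negative (kept, but worth inspecting)."""
        return self.residence_days < 0


def phenology_table(
    coastal: pd.DataFrame,
    riverine: pd.DataFrame,
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per region-year MDMTs and residence times from long-format catch data.

    ``coastal``/``riverine`` need columns (region, year, value) in date order
    within each region-year; ``labels`` (year, label) attaches regimes.
    Region-years with zero total catch in either series are skipped.
    """
    label_map = (
        dict(zip(labels["year"].astype(int), labels["label"]))
        if labels is not None
        else {}
    )
    sort_col = "day" if "day" in coastal.columns else "date"
    riv_groups = {
        key: grp for key, grp in riverine.groupby(["region", "year"], sort=True)
    }
    rows = []
    for (region, year), grp in coastal.groupby(["region", "year"], sort=True):
        riv = riv_groups.get((region, year))
        if riv is None:
            continue
        try:
            c = mdmt(grp.sort_values(sort_col)["value"].to_numpy())
            r = mdmt(riv.sort_values(sort_col)["value"].to_numpy())
        except UndefinedStatisticError:
            continue
        res = residence_time(c, r)
        rows.append(
            {
                "region": region,
                "year": int(year),
                "regime": label_map.get(int(year), ""),
                "coastal_mdmt": c,
                "riverine_mdmt": r,
                "residence_days": res,
                "flagged": res < 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region", "year", "regime",
            "coastal_mdmt", "riverine_mdmt", "residence_days", "flagged",
        ],
    )


def bin_by_temperature(
    catch: np.ndarray | pd.Series,
    sst: np.ndarray | pd.Series,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Accumulate one aligned (catch, sst) day-series pair into SST bins.

    Bins are left-closed right-open [t, t + width) and labeled by left edge.
    Returns an unnormalized (bin_left, volume) frame covering every visited
    bin, including zero-catch ones.
    """
    catch = np.asarray(catch, dtype=float)
    sst = np.asarray(sst, dtype=float)
    if catch.shape != sst.shape:
        raise DataQualityError(
            f"catch and SST series misaligned: {catch.shape} vs {sst.shape}"
        )
    if bin_width <= 0:
        raise DataQualityError("bin width must be positive")
    left = np.floor(sst / bin_width) * bin_width
    frame = pd.DataFrame({"bin_left": left, "volume": catch})
    out = frame.groupby("bin_left", sort=True)["volume"].sum().reset_index()
    return out


def binned_volumes(
    catch: pd.DataFrame,
    sst: pd.DataFrame,
    labels: pd.DataFrame,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Pooled, normalized migration volume per (region, regime, SST bin).

    Long-format ``catch``/``sst`` (region, year, date, value) are aligned day
    by day within each region-year; each day's catch lands in the bin holding
    that day's SST; bins accumulate over all years of a regime and are then
    normalized to fractions summing to 1 per (region, regime).
    """
    label_map = dict(zip(labels["year"].astype(int), labels["label"]))
    sort_col = "day" if "day" in catch.columns else "date"
    sst_groups = {key: grp for key, grp in sst.groupby(["region", "year"], sort=True)}
    pooled: dict[tuple[str, str], pd.DataFrame] = {}
    for (region, year), grp in catch.groupby(["region", "year"], sort=True):
        regime = label_map.get(int(year))
        if regime is None:
            continue
        s = sst_groups.get((region, year))
        if s is None:
            raise DataQualityError(f"no SST series for {region}/{year}")
        part = bin_by_temperature(
            grp.sort_values(sort_col)["value"].to_numpy(),
            s.sort_values(sort_col)["value"].to_numpy(),
            bin_width=bin_width,
        )
        key = (region, regime)
        pooled[key] = (
            part
            if key not in pooled
            else (
                pd.concat([pooled[key], part])
                .groupby("bin_left", sort=True)["volume"]
                .sum()
                .reset_index()
            )
        )
    rows = []
    for (region, regime), frame in sorted(pooled.items()):
        total = frame["volume"].sum()
        if total > 0:
            frame = frame.assign(volume=frame["volume"] / total)
        rows.append(frame.assign(region=region, regime=regime))
    if not rows:
        return pd.DataFrame(columns=["region", "regime", "bin_left", "volume"])
    out = pd.concat(rows, ignore_index=True)
    return out[["region", "regime", "bin_left", "volume"]]
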