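"""Study geometry and the Oct-Dec analysis window.

The study area on the eastern and southern coasts of Korea is partitioned into
a northern and a southern area at latitude 37 °N, where the subpolar front sits
during the spawning-migration season.  Six coastal regions (CR1-CR3 north,
CR4-CR6 south) are each described by a lat/lon box (used for averaging gridded
SST) and a representative site point (used for the north/south assignment).

All dates are encoded as integer day offsets from Oct 1 (day 0) of the
migration year; the default window Oct 1 - Dec 31 spans 92 days (days 0..91;
Oct-Dec never contains Feb 29, so the length is year-independent).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import OutOfWindowError, ValidationError

NORTH_LAT_SPLIT = 37.0  # degrees N; subpolar front latitude


@dataclass(frozen=True)
class Region:
    """One coastal study region.

    Parameters
    ----------
    id : str
        Short label, e.g. ``"CR1"``.
    lat_range, lon_range : (float, float)
        Closed box bounds in degrees N / degrees E.
    rep_lat, rep_lon : float
        Representative site point (river mouth); decides the area split.
    area : str
        ``"north"`` or ``"south"``; must agree with ``rep_lat``.
    """

    id: str
    lat_range: tuple[float, float]
    lon_range: tuple[float, float]
    rep_lat: float
    rep_lon: float
    area: str = field(default="")

    def __post_init__(self) -> None:
        expected = "north" if self.rep_lat >= NORTH_LAT_SPLIT else "south"
        if not self.area:
            object.__setattr__(self, "area", expected)
        elif self.area != expected:
            raise ValidationError(
                f"region {self.id}: area={self.area!r} inconsistent with "
                f"representative latitude {self.rep_lat} (split at {NORTH_LAT_SPLIT}N)"
            )
        if not (self.lat_range[0] <= self.lat_range[1]):
            raise ValidationError(f"region {self.id}: bad lat_range {self.lat_range}")
        if not (self.lon_range[0] <= self.lon_range[1]):
            raise ValidationError(f"region {self.id}: bad lon_range {self.lon_range}")

    def contains(self, lat: float, lon: float) -> bool:
        """True if a grid-cell center falls inside the closed box."""
        return (
            self.lat_range[0] <= lat <= self.lat_range[1]
            and self.lon_range[0] <= lon <= self.lon_range[1]
        )


#: (id, box lat, box lon, site point lat, site point lon)
_DEFAULT_GEOMETRY = [
    ("CR1", (38.5, 38.7), (128.4, 128.6), 38.55, 128.41),
    ("CR2", (37.8, 38.0), (128.9, 129.0), 37.86, 128.85),
    ("CR3", (37.4, 37.6), (129.1, 129.3), 37.44, 129.15),
    ("CR4", (37.0, 37.2), (129.5, 129.7), 36.97, 129.41),
    ("CR5", (35.4, 35.6), (129.4, 129.6), 35.47, 129.39),
    ("CR6", (34.9, 35.1), (127.8, 128.0), 34.95, 127.77),
]


def default_registry() -> list[Region]:
    """The six-region study geometry (three per area)."""
    return [
        Region(id=rid, lat_range=lat, lon_range=lon, rep_lat=plat, rep_lon=plon)
        for rid, lat, lon, plat, plon in _DEFAULT_GEOMETRY
    ]


def check_registry(regions: Sequence[Region]) -> None:
    """Validate id uniqueness; raise ValidationError on duplicates."""
    ids = [r.id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate region ids in registry: {ids}")


def regions_by_area(regions: Sequence[Region]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {"north": [], "south": []}
    for r in regions:
        out[r.area].append(r.id)
    return out


def resolve_ids(regions: Sequence[Region], ids: Iterable[str]) -> None:
    """Referential-integrity check: every id must resolve in the registry."""
    known = {r.id for r in regions}
    unknown = sorted(set(ids) - known)
    if unknown:
        raise ValidationError(f"region ids not in registry: {unknown}")


@dataclass(frozen=True)
class AnalysisWindow:
    """Oct 1 - Dec 31 analysis window of one migration year."""

    year: int
    start_month: int = 10
    start_day: int = 1
    end_month: int = 12
    end_day: int = 31

    @property
    def start(self) -> dt.date:
        return dt.date(self.year, self.start_month, self.start_day)

    @property
    def end(self) -> dt.date:
        return dt.date(self.year, self.end_month, self.end_day)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("window start must precede end within one year")

    def __len__(self) -> int:
        return (self.end - self.start).days + 1

    def day_index(self, date: dt.date) -> int:
        """0-based days since window start; raises if ``date`` is outside."""
        if date < self.start or date > self.end:
            raise OutOfWindowError(f"{date} outside window {self.start}..{self.end}")
        return (date - self.start).days

    def date_at(self, day: int) -> dt.date:
        """Inverse of :meth:`day_index`."""
        if not 0 <= day < len(self):
            raise OutOfWindowError(f"day {day} outside 0..{len(self) - 1}")
        return self.start + dt.timedelta(days=day)


WINDOW_LENGTH = 92  # days in the default Oct 1 - Dec 31 window


def day_index(date: dt.date, window: AnalysisWindow) -> int:
    return window.day_index(date)


# ---------------------------------------------------------------------------
# registry serialization


def registry_to_dicts(regions: Sequence[Region]) -> list[dict]:
    return [
        {
            "id": r.id,
            "lat_range": list(r.lat_range),
            "lon_range": list(r.lon_range),
            "rep_lat": r.rep_lat,
            "rep_lon": r.rep_lon,
            "area": r.area,
        }
        for r in regions
    ]


def registry_from_dicts(records: Iterable[dict]) -> list[Region]:
    regions = [
        Region(
            id=d["id"],
            lat_range=tuple(d["lat_range"]),
            lon_range=tuple(d["lon_range"]),
            rep_lat=d["rep_lat"],
            rep_lon=d["rep_lon"],
            area=d.get("area", ""),
        )
        for d in records
    ]
    check_registry(regions)
    return regions


def save_registry(regions: Sequence[Region], path: str | Path) -> None:
    path = Path(path)
    data = registry_to_dicts(regions)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_registry(path: str | Path) -> list[Region]:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return registry_from_dicts(data)


# ---------------------------------------------------------------------------
# gridded-SST box averaging (optional adapter; needs xarray datasets)


def extract_box_means(
    dataset,
    regions: Sequence[Region],
    sst_var: str = "analysed_sst",
    lat_name: str = "lat",
    lon_name: str = "lon",
    time_name: str = "time",
) -> pd.DataFrame:
    """Average a gridded SST field over each region box.

    ``dataset`` is an xarray Dataset with 1-D lat/lon coordinates and a time
    axis.  All grid cells whose centers fall inside a region's closed box are
    averaged.  Returns a long-format frame (region, date, sst).
    """
    lats = dataset[lat_name].values
    lons = dataset[lon_name].values
    times = pd.to_datetime(dataset[time_name].values)
    frames = []
    for region in regions:
        lat_mask = (lats >= region.lat_range[0]) & (lats <= region.lat_range[1])
        lon_mask = (lons >= region.lon_range[0]) & (lons <= region.lon_range[1])
        if not lat_mask.any() or not lon_mask.any():
            raise ValidationError(f"no grid cells fall inside region {region.id}")
        sub = dataset[sst_var].isel(
            {lat_name: lat_mask.nonzero()[0], lon_name: lon_mask.nonzero()[0]}
        )
        mean = sub.mean(dim=[lat_name, lon_name]).values
        frames.append(
            pd.DataFrame({"region": region.id, "date": times.date, "sst": mean})
        )
    return pd.concat(frames, ignore_index=True)
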