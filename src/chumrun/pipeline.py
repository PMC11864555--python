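"""End-to-end orchestration: data -> regime typing -> phenology -> models.

A single PipelineConfig drives the run: either a synthetic-scenario preset or
input CSV paths (exclusively).  All stage outputs (crossings, labels,
phenology, bins, model tables) are written as CSV next to the JSON report so
every stage is independently inspectable, and identical config + seed yields
a byte-identical report payload.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ChumrunError, FitError, ValidationError
from .lme import MixedModelSelector, significance_tier
from .phenology import binned_volumes, phenology_table
from .regimes import DEFAULT_NS_GAP, DEFAULT_THRESHOLD, label_years
from .regions import WINDOW_LENGTH, Region, default_registry, load_registry, resolve_ids
from .simulate import PRESET_NAMES, make_scenario_preset, read_long_csv, simulate_dataset
from .thermal import (
    FAMILIES,
    family_comparison_table,
    fit_response,
    peak_temperature,
)

log = logging.getLogger("chumrun.pipeline")


@dataclass
class PipelineConfig:
    """Everything a run needs; preset and input paths are mutually exclusive."""

    preset: Optional[str] = None
    sst_path: Optional[str] = None
    coastal_path: Optional[str] = None
    riverine_path: Optional[str] = None
    regions_path: Optional[str] = None
    threshold: float = DEFAULT_THRESHOLD
    ns_gap_threshold: float = DEFAULT_NS_GAP
    bin_width: float = 1.0
    structures: Sequence[int] = (1, 2, 3)
    families: Sequence[str] = FAMILIES
    responses: Sequence[str] = ("coastal_mdmt", "residence_days")
    out_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        paths = [self.sst_path, self.coastal_path, self.riverine_path]
        if self.preset is not None and any(paths):
            raise ValidationError("give either a scenario preset or input paths, not both")
        if self.preset is None and not all(paths):
            raise ValidationError(
                "need a preset or all three input paths (sst, coastal, riverine)"
            )
        if self.preset is not None and self.preset not in PRESET_NAMES:
            raise ValidationError(f"unknown preset {self.preset!r}; know {PRESET_NAMES}")
        for value, name in [
            (self.threshold, "threshold"),
            (self.ns_gap_threshold, "ns_gap_threshold"),
            (self.bin_width, "bin_width"),
        ]:
            if value <= 0:
                raise ValidationError(f"{name} must be positive, got {value}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["structures"] = list(self.structures)
        d["families"] = list(self.families)
        d["responses"] = list(self.responses)
        return d

    def config_hash(self) -> str:
        body = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(body.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunReport:
    """All result tables of one pipeline run plus provenance."""

    labels: list
    phenology: list
    lme_comparison: dict
    lme_contrasts: dict
    nla_comparison: list
    nla_coefficients: list
    peak_temperatures: list
    provenance: dict
    truth_check: Optional[dict] = None

    def to_json(self) -> str:
        def np_default(obj):
            if isinstance(obj, np.generic):
                return obj.item()
            raise TypeError(f"not JSON-serializable: {type(obj)}")

        return json.dumps(
            dataclasses.asdict(self), indent=2, sort_keys=True, default=np_default
        )


def validate_inputs(
    paths: dict[str, str | Path], regions: Sequence[Region] | None = None
) -> dict[str, dict]:
    """Schema/coverage/sign checks per file; {name: {passed, messages}}."""
    regions = list(regions) if regions is not None else default_registry()
    summary: dict[str, dict] = {}
    for name, path in paths.items():
        messages: list[str] = []
        try:
            df = read_long_csv(path)
        except (OSError, ValidationError) as exc:
            summary[name] = {"passed": False, "messages": [str(exc)]}
            continue
        try:
            resolve_ids(regions, df["region"].unique())
        except ValidationError as exc:
            messages.append(str(exc))
        is_catch = name != "sst"
        relevant = df[df["location"] != "sst"] if is_catch else df[df["location"] == "sst"]
        if relevant.empty:
            relevant = df
        if is_catch:
            bad = relevant[relevant["value"] < 0]
            if not bad.empty:
                rows = bad.index[:5].tolist()
                messages.append(f"negative catch values at rows {rows}")
        for (region, year, loc), grp in relevant.groupby(["region", "year", "location"]):
            n_days = grp["date"].nunique()
            if loc == "sst":
                # missing days count against the 3-day interpolation limit
                if n_days < WINDOW_LENGTH - 3:
                    messages.append(
                        f"{region}/{year}/{loc}: only {n_days}/{WINDOW_LENGTH} days "
                        "(gap exceeds the 3-day interpolation limit)"
                    )
            elif n_days < WINDOW_LENGTH:
                messages.append(
                    f"{region}/{year}/{loc}: only {n_days}/{WINDOW_LENGTH} days covered"
                )
        summary[name] = {"passed": not messages, "messages": messages}
    return summary


def _location_frame(data: pd.DataFrame, location: str) -> pd.DataFrame:
    return data[data["location"] == location].copy()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; any failure aborts with the stage named."""
    logging.basicConfig(level=config.log_level)
    t_start = time.perf_counter()
    regions = (
        load_registry(config.regions_path) if config.regions_path else default_registry()
    )
    outdir = Path(config.out_dir) if config.out_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # -- stage: data ---------------------------------------------------------
    stage = "data"
    truth = None
    try:
        if config.preset:
            scenario = make_scenario_preset(config.preset, seed=config.seed)
            dataset = simulate_dataset(scenario)
            data = dataset.data
            truth = dataset.truth
            if outdir:
                dataset.write(outdir)
        else:
            frames = []
            for loc, path in [
                ("sst", config.sst_path),
                ("coast", config.coastal_path),
                ("river", config.riverine_path),
            ]:
                df = read_long_csv(path)
                if set(df["location"].unique()) - {loc}:
                    df = df[df["location"] == loc]
                frames.append(df)
            data = pd.concat(frames, ignore_index=True).drop_duplicates()
            resolve_ids(regions, data["region"].unique())
    except ChumrunError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc
    log.info("stage %s done (%.2fs)", stage, time.perf_counter() - t_start)

    # -- stage: regime typing ------------------------------------------------
    stage = "type-years"
    t0 = time.perf_counter()
    try:
        crossings, labels = label_years(
            _location_frame(data, "sst"),
            threshold=config.threshold,
            ns_gap_threshold=config.ns_gap_threshold,
            regions=regions,
        )
    except ChumrunError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc
    if outdir:
        crossings.to_csv(outdir / "crossings.csv", index=False)
        labels.to_csv(outdir / "labels.csv", index=False)
    log.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)

    # -- stage: phenology ----------------------------------------------------
    stage = "phenology"
    t0 = time.perf_counter()
    try:
        phen = phenology_table(
            _location_frame(data, "coast"), _location_frame(data, "river"), labels
        )
    except ChumrunError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc
    if outdir:
        phen.to_csv(outdir / "phenology.csv", index=False)
    log.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)

    # -- stage: mixed models -------------------------------------------------
    stage = "fit-lme"
    t0 = time.perf_counter()
    lme_comparison: dict = {}
    lme_contrasts: dict = {}
    try:
        for response in config.responses:
            selector = MixedModelSelector(
                response=response, structures=tuple(config.structures)
            ).fit(phen)
            lme_comparison[response] = selector.comparison_.to_dict("records")
            lme_contrasts[response] = selector.selected_.contrasts.to_dict("records")
            if outdir:
                selector.comparison_.to_csv(
                    outdir / f"lme_comparison_{response}.csv", index=False
                )
                selector.selected_.contrasts.to_csv(
                    outdir / f"lme_contrasts_{response}.csv", index=False
                )
    except ChumrunError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc
    log.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)

    # -- stage: thermal response ---------------------------------------------
    stage = "fit-nla"
    t0 = time.perf_counter()
    nla_rows: list = []
    coef_rows: list = []
    peak_rows: list = []
    try:
        for location in ("coast", "river"):
            bins = binned_volumes(
                _location_frame(data, location),
                _location_frame(data, "sst"),
                labels,
                bin_width=config.bin_width,
            )
            if outdir:
                bins.to_csv(outdir / f"bins_{location}.csv", index=False)
            for (region, regime), grp in bins.groupby(["region", "regime"], sort=True):
                fits = []
                for family in config.families:
                    try:
                        f = fit_response(grp, family, bin_width=config.bin_width)
                        f.location = location
                        fits.append(f)
                    except FitError:
                        continue
                if not fits:
                    continue
                table = family_comparison_table(fits)
                for row in table.to_dict("records"):
                    row.update(region=region, regime=regime, location=location)
                    nla_rows.append(row)
                poly = next((f for f in fits if f.family == "polynomial"), None)
                if poly is not None:
                    for name in ("b1", "b2", "b3"):
                        p = poly.pvalues[name]
                        marker, tier = (
                            significance_tier(p) if np.isfinite(p) else ("", "ns")
                        )
                        coef_rows.append(
                            {
                                "region": region, "regime": regime, "location": location,
                                "term": name,
                                "estimate": poly.coefficients[name],
                                "se": poly.se[name], "p": p,
                                "marker": marker, "tier": tier,
                            }
                        )
                    try:
                        peak = peak_temperature(poly)
                        lo = float(grp["bin_left"].min()) + config.bin_width / 2
                        hi = float(grp["bin_left"].max()) + config.bin_width / 2
                        peak_rows.append(
                            {
                                "region": region, "regime": regime,
                                "location": location, "peak_sst": peak,
                                # a vertex outside the observed bins means the
                                # response was effectively monotone there
                                "in_range": bool(lo <= peak <= hi),
                            }
                        )
                    except FitError:
                        pass
    except ChumrunError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc
    log.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)

    # -- report ---------------------------------------------------------------
    truth_check = None
    if truth is not None:
        label_map = dict(zip(labels["year"].astype(int), labels["label"]))
        hits = sum(
            1
            for y, lab in truth["regimes"].items()
            if label_map.get(int(y)) == lab
        )
        truth_check = {
            "label_accuracy": hits / len(truth["regimes"]),
            "n_years": len(truth["regimes"]),
        }

    report = RunReport(
        labels=labels.to_dict("records"),
        phenology=phen.drop(columns=["flagged"]).assign(
            flagged=phen["flagged"].astype(bool)
        ).to_dict("records"),
        lme_comparison=lme_comparison,
        lme_contrasts=lme_contrasts,
        nla_comparison=nla_rows,
        nla_coefficients=coef_rows,
        peak_temperatures=peak_rows,
        provenance={
            "package_version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        truth_check=truth_check,
    )
    if outdir:
        (outdir / "report.json").write_text(report.to_json())
    log.info("pipeline done (%.2fs total)", time.perf_counter() - t_start)
    return report
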