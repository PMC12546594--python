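"""End-to-end orchestration: synthesize → drivers → ITS → exposure.

`run_all` produces, under one output directory:

* ``world/`` — the synthetic fixture bundle (tables, AEI, climate cubes
  for the six factorial experiments);
* ``rates_<scenario>.csv`` — per-country annual flood-reduction rates
  per 5-year window, from the socioeconomic PCA + factor table;
* ``its_<scenario>.nc`` — annual per-cell technique shares;
* ``exposure/`` — percentile thresholds, exceedance-hour fields per
  experiment/member/variable, forcing-contrast impact fields with
  ensemble-agreement masks, hotspot masks, regional exposure series and
  irrigation-water-withdrawal aggregates;
* ``manifest.json`` — seed, config hash, per-file checksums.

Everything is deterministic given the seed; re-running reproduces
identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from . import heat_exposure as hx
from . import its_engine, synthetic_world, transition_drivers
from .errors import ConfigurationError, InputError, IrriheatError
from .synthetic_world import (
    EXPERIMENTS,
    InjectedSignal,
    World,
    WorldConfig,
    generate_climate_cube,
    generate_world,
    write_fixture_bundle,
)
from .transition_drivers import FactorTable, SocioEconomicIndex

# toy withdrawal model: application depth (mm yr-1 over irrigated area)
# by technique; efficient techniques apply less water
APPLICATION_DEPTH = {"drip": 350.0, "sprinkler": 500.0, "flood": 700.0}

CONTRASTS = {
    "irrigation_Hist": ("Hist_IRR", "Hist_NOI"),
    "irrigation_SSP1": ("SSP1_IRR", "SSP1_NOI"),
    "irrigation_SSP3": ("SSP3_IRR", "SSP3_NOI"),
    "forcings_SSP1": ("SSP1_IRR", "Hist_IRR"),
    "forcings_SSP3": ("SSP3_IRR", "Hist_IRR"),
    "scenario": ("SSP3_IRR", "SSP1_IRR"),
}


@dataclass
class RunConfig:
    world: WorldConfig = field(default_factory=WorldConfig.toy)
    signal: InjectedSignal = field(default_factory=InjectedSignal)
    factor_table: FactorTable = field(default_factory=FactorTable.default)
    its_years: tuple[int, int] = (2015, 2070)
    variables: tuple[str, ...] = ("T2m", "Tw")
    hotspot_thresh: float = 0.2


class StageError(IrriheatError):
    """A pipeline stage failed; the message is tagged with the stage."""


class _Stage:
    """Marks files written by a failing stage with a .partial suffix."""

    def __init__(self, name: str, outdir: Path):
        self.name, self.outdir = name, Path(outdir)

    def __enter__(self):
        self.before = {p for p in self.outdir.rglob("*") if p.is_file()}
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is None:
            return False
        for p in {q for q in self.outdir.rglob("*") if q.is_file()} - self.before:
            p.rename(p.with_name(p.name + ".partial"))
        raise StageError(f"[{self.name}] {exc}") from exc


def _precip20(countries: pd.DataFrame, scenario: str,
              year: int) -> pd.Series:
    """20-year-mean precipitation per country for the window ending at
    ``year`` (inclusive), from the 5-yearly samples."""
    sub = countries[(countries["scenario"] == scenario)
                    & (countries["year"] > year - 20)
                    & (countries["year"] <= year)]
    return sub.groupby("country")["precip"].mean()


def compute_rates(countries: pd.DataFrame, table: FactorTable,
                  scenario: str, window_years) -> pd.DataFrame:
    """Annual flood-reduction rate per country per 5-year window.

    The socioeconomic PCA and both normalisation baselines are fixed on
    the 2010 history (identical across scenarios) and frozen; each
    window year is projected with the frozen model.
    """
    base = countries[(countries["scenario"] == "SSP1")
                     & (countries["year"] == 2010)].sort_values("country")
    model = SocioEconomicIndex().fit(base)
    socio_baseline = model.transform(base)
    hydro_baseline = _precip20(countries, "SSP1", 2010).to_numpy()

    frames = []
    for year in window_years:
        rows = countries[(countries["scenario"] == scenario)
                         & (countries["year"] == year)].sort_values("country")
        if rows.empty:
            raise ConfigurationError(f"no driver data for window {year}")
        drv = rows.loc[:, ["country", "year", "gdp", "gov", "urb", "gii"]]
        drv = drv.copy()
        p20 = _precip20(countries, scenario, year)
        drv["precip20"] = drv["country"].map(p20)
        frames.append(transition_drivers.rates_for_countries(
            drv, model, socio_baseline, hydro_baseline, table))
    return pd.concat(frames, ignore_index=True)


def build_its(world: World, rates: pd.DataFrame,
              years: tuple[int, int]) -> xr.DataArray:
    """Annual per-cell technique shares for one scenario's rate table."""
    share_map = world.country_shares.set_index("country")
    country_arr = share_map.loc[
        world.cells["country"], ["drip", "sprinkler", "flood"]
    ].to_numpy()
    baseline = its_engine.baseline_assign(country_arr, world.cft)
    return its_engine.build_transient_its(
        baseline, rates, world.cft, years,
        cell_country=world.cells["country"].to_numpy(),
    )


def iww_depth(world: World, its: xr.DataArray, scenario: str) -> xr.DataArray:
    """Withdrawal depth (mm yr⁻¹ over the full cell) per cell and year.

    Toy model: AEI fraction × technique-share-weighted application depth.
    """
    depths = xr.DataArray(
        [APPLICATION_DEPTH[t] for t in its["technique"].to_numpy()],
        dims=("technique",), coords={"technique": its["technique"]},
    )
    applied = (its * depths).sum("technique")       # (year, cell), mm yr-1
    aei = world.aei.sel(scenario=scenario).interp(year=its["year"])
    return (applied * aei).rename("iww_depth")


def _cell_to_grid(da: xr.DataArray, config: WorldConfig) -> xr.DataArray:
    """Reshape a trailing row-major cell dim onto (lat, lon)."""
    stacked = da.transpose(..., "cell")
    data = stacked.to_numpy().reshape(
        stacked.shape[:-1] + (config.nlat, config.nlon))
    coords = {k: v for k, v in stacked.coords.items() if "cell" not in v.dims}
    coords["lat"] = np.arange(config.nlat)
    coords["lon"] = np.arange(config.nlon)
    return xr.DataArray(data, dims=stacked.dims[:-1] + ("lat", "lon"),
                        coords=coords, name=da.name)


def run_all(config: RunConfig, outdir, seed: int | None = None) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    if seed is not None:
        config = dataclasses.replace(
            config, world=dataclasses.replace(config.world, rng_seed=seed))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world_dir = outdir / "world"
    expo_dir = outdir / "exposure"
    world_dir.mkdir(exist_ok=True)
    expo_dir.mkdir(exist_ok=True)

    with _Stage("synthetic_world", outdir):
        world = generate_world(config.world, config.signal)
        cubes = {(exp, m): generate_climate_cube(world, exp, m)
                 for exp in EXPERIMENTS
                 for m in range(config.world.n_ensemble)}
        write_fixture_bundle(world, world_dir, cubes)

    with _Stage("transition_drivers", outdir):
        window_years = range(2010, config.its_years[1], 5)
        rates = {}
        for scen in synthetic_world.SCENARIOS:
            rates[scen] = compute_rates(world.countries, config.factor_table,
                                        scen, window_years)
            rates[scen].to_csv(outdir / f"rates_{scen}.csv", index=False)

    with _Stage("its_engine", outdir):
        its = {}
        for scen in synthetic_world.SCENARIOS:
            its[scen] = build_its(world, rates[scen], config.its_years)
            its[scen].to_dataset(name="its").to_netcdf(
                outdir / f"its_{scen}.nc")

    with _Stage("heat_exposure", outdir):
        for (exp, m), cube in cubes.items():
            cube["Tw"] = hx.wet_bulb(cube["T2m"], cube["RH"])
        noi_hist = [cubes[("Hist_NOI", m)]
                    for m in range(config.world.n_ensemble)]
        thresholds = xr.Dataset({
            var: hx.reference_threshold(hx.pool_noi(noi_hist, var))
            for var in config.variables
        })
        thresholds.to_netcdf(expo_dir / "thresholds.nc")

        exposure = {}
        for exp in EXPERIMENTS:
            for var in config.variables:
                per_member = xr.concat(
                    [hx.exceedance_hours(cubes[(exp, m)], thresholds[var],
                                         var, config.world.timestep_hours)
                     for m in range(config.world.n_ensemble)],
                    dim="member")
                per_member = per_member.assign_coords(
                    member=np.arange(config.world.n_ensemble))
                exposure[(exp, var)] = per_member
                per_member.to_dataset(name="hours").to_netcdf(
                    expo_dir / f"exposure_{exp}_{var}.nc")

        for name, (a, b) in CONTRASTS.items():
            for var in config.variables:
                member_impact = hx.impact_difference(
                    exposure[(a, var)], exposure[(b, var)])
                ds = xr.Dataset({
                    "impact": member_impact.mean("member"),
                    "impact_members": member_impact,
                    "agreement": hx.agreement_mask(member_impact),
                })
                ds.to_netcdf(expo_dir / f"impact_{name}_{var}.nc")

        aei_hist = _cell_to_grid(
            world.aei.sel(scenario="SSP1", year=2010), config.world)
        hotspot = {}
        for scen in synthetic_world.SCENARIOS:
            aei_fut = _cell_to_grid(
                world.aei.sel(scenario=scen, year=2070), config.world)
            hotspot[scen] = hx.classify_hotspots(
                aei_hist, aei_fut, config.hotspot_thresh)
            hotspot[scen].astype(str).to_dataset().to_netcdf(
                expo_dir / f"hotspots_{scen}.nc")

        areas = xr.DataArray(
            np.full((config.world.nlat, config.world.nlon),
                    config.world.cell_area_km2),
            dims=("lat", "lon"))
        series_rows = []
        for exp in EXPERIMENTS:
            scen = exp.split("_")[0]
            mask = (hotspot.get(scen, hotspot["SSP1"]) == "traditional")
            for var in config.variables:
                ts = hx.area_mean(exposure[(exp, var)], mask, areas)
                med = ts.median("member")
                vals = med.to_numpy()
                smooth = (hx.savgol_smooth(vals) if vals.size >= 7 else vals)
                for y, raw, sm in zip(med["year"].to_numpy(), vals, smooth):
                    series_rows.append(dict(experiment=exp, variable=var,
                                            year=int(y), hours=float(raw),
                                            hours_smooth=float(sm)))
        pd.DataFrame(series_rows).to_csv(
            expo_dir / "hotspot_series.csv", index=False)

        iww_rows = []
        areas_cell = xr.DataArray(
            world.cells["area_km2"].to_numpy(), dims=("cell",))
        for scen in synthetic_world.SCENARIOS:
            depth = iww_depth(world, its[scen], scen)
            regions = world.cells["country"].to_numpy()
            for y in depth["year"].to_numpy():
                d = depth.sel(year=y)
                total = hx.aggregate_iww(d, areas_cell)
                row = dict(scenario=scen, year=int(y),
                           global_km3=float(total))
                for name in sorted(set(regions)):
                    m = xr.DataArray(regions == name, dims=("cell",))
                    row[f"region_{name}_km3"] = float(
                        hx.aggregate_iww(d, areas_cell, m))
                iww_rows.append(row)
        pd.DataFrame(iww_rows).to_csv(expo_dir / "iww.csv", index=False)

    with _Stage("manifest", outdir):
        manifest = {
            "version": __version__,
            "seed": config.world.rng_seed,
            "config_hash": hashlib.sha256(
                json.dumps(dataclasses.asdict(config), sort_keys=True,
                           default=str).encode()).hexdigest(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
            "checksums": {
                str(p.relative_to(outdir)):
                    hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(outdir.rglob("*"))
                if p.is_file() and p.name != "manifest.json"
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_outputs(outdir) -> ValidationReport:
    """Re-check module invariants on a finished run directory.

    Verifies the share simplex and suitability caps of every ITS file,
    exposure bounds and timestep granularity, global-equals-sum-of-
    regions withdrawal additivity, and the manifest checksums.
    """
    outdir = Path(outdir)
    rep = ValidationReport()
    if not outdir.is_dir():
        raise OSError(f"not a directory: {outdir}")

    try:
        cells = pd.read_csv(outdir / "world" / "cells.csv")
        cft = cells[["f_drip", "f_sprinkler", "f_flood"]].to_numpy()
    except OSError as e:
        raise OSError(f"unreadable bundle: {e}") from e

    for path in sorted(outdir.glob("its_*.nc")):
        try:
            its = xr.open_dataset(path)["its"]
        except Exception as e:  # noqa: BLE001 - report, don't crash
            rep.violations.append(f"{path.name}: unreadable ({e})")
            continue
        arr = its.transpose("year", "cell", "technique").to_numpy()
        if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
            rep.violations.append(f"{path.name}: shares outside [0, 1]")
        if np.any(np.abs(arr.sum(axis=-1) - 1) > 1e-6):
            rep.violations.append(f"{path.name}: share simplex violated")
        if np.any(arr[..., 0] > cft[None, :, 0] + 1e-6):
            rep.violations.append(f"{path.name}: drip cap violated")
        if np.any(arr[..., 0] + arr[..., 1]
                  > cft[None, :, 0] + cft[None, :, 1] + 1e-6):
            rep.violations.append(f"{path.name}: sprinkler cap violated")

    for path in sorted((outdir / "exposure").glob("exposure_*.nc")):
        try:
            hours = xr.open_dataset(path)["hours"].to_numpy()
        except Exception as e:  # noqa: BLE001
            rep.violations.append(f"{path.name}: unreadable ({e})")
            continue
        if np.any(hours < 0) or np.any(hours > hx.HOURS_PER_YEAR):
            rep.violations.append(f"{path.name}: exposure outside [0, 8760]")
        if np.any(np.abs(hours / 3.0 - np.round(hours / 3.0)) > 1e-9):
            rep.violations.append(f"{path.name}: not a multiple of 3 h")

    iww_path = outdir / "exposure" / "iww.csv"
    if iww_path.exists():
        iww = pd.read_csv(iww_path)
        regional = iww.filter(like="region_").sum(axis=1)
        if np.any(np.abs(regional - iww["global_km3"]) > 1e-9):
            rep.violations.append("iww.csv: global != sum of regions")
    else:
        rep.violations.append("missing exposure/iww.csv")

    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        for rel, digest in manifest.get("checksums", {}).items():
            p = outdir / rel
            if not p.exists():
                rep.violations.append(f"manifest: missing file {rel}")
            elif hashlib.sha256(p.read_bytes()).hexdigest() != digest:
                rep.violations.append(f"manifest: checksum mismatch {rel}")
    else:
        rep.violations.append("missing manifest.json")
    return rep
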