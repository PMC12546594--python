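"""Self-contained toy world for end-to-end testing of the pipeline.

Real inputs to the scenario generator and exposure diagnostics are
country socioeconomic trajectories, gridded irrigation extent (AEI) and
crop suitability, and 3-hourly climate cubes from paired Earth-system
experiments. This module fabricates all of them at desk scale with a
known ground truth, so that every downstream stage can be verified:

* countries whose SSP1 trajectories develop faster (GDP/governance/
  urbanisation up, gender inequality down) than their SSP3 ones,
  identical at the 2010 branch point;
* a rectangular grid partitioned into country blocks, with AEI constant
  under SSP1 and expanding under SSP3 for a designated late-developing
  country (the "emerging hotspot"), and crop-functional-type (CFT)
  compositions spanning pure-flood, mixed and pure-drip cells;
* climate cubes for the six factorial experiments (Hist/SSP1/SSP3 ×
  IRR/NOI, several ensemble members), built from a seasonal + diurnal
  sinusoid plus AR(1) weather noise, a scenario warming trend, and — in
  the IRR members only — an injected irrigation signal: cooling δT (°C)
  and moistening δRH (%) scaled by the cell's irrigated fraction, plus
  optional zero-mean noise. IRR and NOI share the weather noise draw per
  member (common random numbers), so IRR − NOI recovers the injected
  signal exactly in the noiseless case.

The calendar is a 365-day no-leap year: 2920 3-hourly blocks per year.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy.signal import lfilter

from .errors import ConfigurationError, InputError

SCENARIOS = ("SSP1", "SSP3")
EXPERIMENTS = ("Hist_IRR", "Hist_NOI", "SSP1_IRR", "SSP1_NOI",
               "SSP3_IRR", "SSP3_NOI")
DRIVER_YEARS = tuple(range(1990, 2101, 5))
AEI_YEARS = tuple(range(2010, 2101, 5))
_SCEN_CODE = {"Hist": 0, "SSP1": 1, "SSP3": 2}


@dataclass(frozen=True)
class WorldConfig:
    """Dimensions, periods and seed of the toy world.

    The historical and future climate periods must be contiguous and
    non-overlapping; the grid must hold at least one cell per country.
    Default periods follow the experiment design (1985–2014 historical,
    2015–2074 future); :meth:`toy` gives the 2-year-per-period desk-scale
    variant used by the default pipeline and the test-suite.
    """

    n_countries: int = 5
    nlat: int = 8
    nlon: int = 10
    cell_area_km2: float = 1000.0
    years_hist: tuple[int, int] = (1985, 2014)
    years_future: tuple[int, int] = (2015, 2074)
    n_ensemble: int = 3
    timestep_hours: int = 3
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_countries < 2:
            raise ConfigurationError("need at least 2 countries")
        if self.n_ensemble < 1:
            raise ConfigurationError("need at least 1 ensemble member")
        if 24 % self.timestep_hours != 0:
            raise ConfigurationError("timestep must divide 24 hours")
        h0, h1 = self.years_hist
        f0, f1 = self.years_future
        if not (h0 <= h1 and f0 <= f1):
            raise ConfigurationError("year ranges must be increasing")
        if f0 != h1 + 1:
            raise ConfigurationError(
                "historical and future periods must be contiguous and "
                "non-overlapping"
            )
        if self.nlat * self.nlon < self.n_countries:
            raise ConfigurationError("grid smaller than the country count")

    @classmethod
    def toy(cls, rng_seed: int = 0, **overrides) -> "WorldConfig":
        """Desk-scale config: 2 synthetic climate years per period."""
        kw = dict(years_hist=(2013, 2014), years_future=(2015, 2016),
                  rng_seed=rng_seed)
        kw.update(overrides)
        return cls(**kw)

    @property
    def blocks_per_year(self) -> int:
        return 365 * 24 // self.timestep_hours

    @property
    def n_cells(self) -> int:
        return self.nlat * self.nlon


@dataclass(frozen=True)
class InjectedSignal:
    """Ground-truth irrigation effect written into the IRR cubes.

    ``delta_t`` (°C, negative = evaporative cooling) and ``delta_rh``
    (%, positive = moistening) apply over irrigated cells, scaled
    linearly by the cell's AEI fraction; independent Gaussian noise of
    the given standard deviations is added on top per 3-hourly block.
    """

    delta_t: float = -1.0
    delta_rh: float = 5.0
    noise_sd_t: float = 0.5
    noise_sd_rh: float = 1.0

    @classmethod
    def noiseless(cls, delta_t: float = -1.0,
                  delta_rh: float = 5.0) -> "InjectedSignal":
        return cls(delta_t=delta_t, delta_rh=delta_rh,
                   noise_sd_t=0.0, noise_sd_rh=0.0)


def _rng(config: WorldConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.rng_seed, spawn_key=key)
    )


def generate_countries(config: WorldConfig) -> pd.DataFrame:
    """Country socioeconomic and precipitation trajectories.

    One row per country x scenario x 5-year step (1990–2100), columns
    gdp (index), gov, urb, gii (all 0–1 indices except gdp) and precip
    (mm yr⁻¹). Shared history through 2010; from 2015 the SSP1 branch
    develops strictly faster than SSP3.
    """
    rng = _rng(config, 0)
    n = config.n_countries
    # the four indicators share a latent development level (they are
    # strongly correlated in reality, which is what makes a single
    # principal component meaningful); GII loads negatively on it
    level = rng.normal(0.0, 1.0, n)
    gdp0 = np.maximum(18.0 + 9.0 * level + rng.normal(0, 2.0, n), 1.0)
    gov0 = np.clip(0.50 + 0.12 * level + rng.normal(0, 0.03, n), 0.05, 0.95)
    urb0 = np.clip(0.50 + 0.12 * level + rng.normal(0, 0.03, n), 0.05, 0.95)
    gii0 = np.clip(0.45 - 0.10 * level + rng.normal(0, 0.03, n), 0.05, 0.95)
    precip0 = rng.uniform(300.0, 1500.0, n)   # mm yr-1
    g_ssp3 = rng.uniform(0.02, 0.06, n)       # 5-year GDP growth, SSP3
    g_ssp1 = g_ssp3 + rng.uniform(0.08, 0.15, n)
    p_trend = rng.uniform(-0.002, 0.002, n)   # fractional change / yr

    rows = []
    for scen in SCENARIOS:
        for year in DRIVER_YEARS:
            steps = (year - 2010) / 5.0  # negative in history
            if year <= 2010:
                gdp = gdp0 * (1.0 + 0.05) ** steps
                gov, urb, gii = gov0 + 0.01 * steps, urb0 + 0.01 * steps, gii0
            elif scen == "SSP1":
                gdp = gdp0 * (1.0 + g_ssp1) ** steps
                gov = 1.0 - (1.0 - gov0) * np.exp(-0.08 * steps)
                urb = 1.0 - (1.0 - urb0) * np.exp(-0.08 * steps)
                gii = gii0 * np.exp(-0.10 * steps)
            else:
                gdp = gdp0 * (1.0 + g_ssp3) ** steps
                gov = 1.0 - (1.0 - gov0) * np.exp(-0.02 * steps)
                urb = 1.0 - (1.0 - urb0) * np.exp(-0.02 * steps)
                gii = np.clip(gii0 * (1.0 + 0.01 * steps), 0.0, 1.0)
            precip = precip0 * (1.0 + p_trend * (year - 2010))
            for i in range(n):
                rows.append(
                    dict(country=f"C{i:02d}", scenario=scen, year=year,
                         gdp=gdp[i], gov=np.clip(gov[i], 0, 1),
                         urb=np.clip(urb[i], 0, 1), gii=float(gii[i]),
                         precip=max(precip[i], 1.0))
                )
    return pd.DataFrame(rows)


def generate_grid(config: WorldConfig,
                  countries: pd.DataFrame) -> tuple[pd.DataFrame, xr.DataArray]:
    """Cell table and AEI trajectories.

    Cells are assigned to countries in contiguous blocks. The first
    country is the traditional irrigation hotspot (AEI 0.25–0.5); the
    last is the emerging one, whose AEI expands under SSP3 from 0.05 to
    0.55 by 2070 (constant under SSP1, like everyone else). CFT
    compositions cycle through pure-flood, pure-drip and random mixed
    cells. Per-cell climatological normals (t_base °C, rh_base %) are
    drawn here so that all climate cubes share them.
    """
    names = sorted(countries["country"].unique())
    if len(names) != config.n_countries:
        raise ConfigurationError("country table does not match the config")
    rng = _rng(config, 1)
    n_cells = config.n_cells
    cell_country = np.repeat(
        np.arange(config.n_countries),
        np.diff(np.linspace(0, n_cells, config.n_countries + 1).astype(int)),
    )

    cft = np.empty((n_cells, 3))
    for j in range(n_cells):
        if j % 5 == 0:
            cft[j] = (0.0, 0.0, 1.0)            # pure flood
        elif j % 5 == 1:
            cft[j] = (1.0, 0.0, 0.0)            # pure drip
        else:
            cft[j] = rng.dirichlet((2.0, 3.0, 3.0))

    aei0 = np.empty(n_cells)
    for j, c in enumerate(cell_country):
        if c == 0:
            aei0[j] = rng.uniform(0.25, 0.50)
        elif c == config.n_countries - 1:
            aei0[j] = 0.05
        else:
            aei0[j] = rng.uniform(0.0, 0.20)

    years = np.array(AEI_YEARS)
    aei = np.empty((len(SCENARIOS), years.size, n_cells))
    for s, scen in enumerate(SCENARIOS):
        for t, year in enumerate(years):
            frac = aei0.copy()
            if scen == "SSP3":
                grow = cell_country == config.n_countries - 1
                ramp = np.clip((year - 2010) / (2070 - 2010), 0.0, 1.0)
                frac[grow] = aei0[grow] + ramp * (0.55 - aei0[grow])
            aei[s, t] = frac
    lat_idx, lon_idx = np.divmod(np.arange(n_cells), config.nlon)
    cells = pd.DataFrame(
        dict(cell=np.arange(n_cells), lat=lat_idx, lon=lon_idx,
             country=[names[c] for c in cell_country],
             area_km2=config.cell_area_km2,
             f_drip=cft[:, 0], f_sprinkler=cft[:, 1], f_flood=cft[:, 2],
             t_base=8.0 + 20.0 * lat_idx / max(config.nlat - 1, 1),
             rh_base=rng.uniform(40.0, 80.0, n_cells))
    )
    aei_da = xr.DataArray(
        aei, dims=("scenario", "year", "cell"),
        coords={"scenario": list(SCENARIOS), "year": years,
                "cell": np.arange(n_cells)},
        name="aei",
    )
    return cells, aei_da


def generate_country_shares(config: WorldConfig,
                            countries: pd.DataFrame) -> pd.DataFrame:
    """Baseline (2010) country-level technique shares, flood-dominated."""
    rng = _rng(config, 2)
    names = sorted(countries["country"].unique())
    drip = rng.uniform(0.03, 0.10, len(names))
    sprink = rng.uniform(0.10, 0.25, len(names))
    return pd.DataFrame(dict(country=names, drip=drip, sprinkler=sprink,
                             flood=1.0 - drip - sprink))


@dataclass
class World:
    config: WorldConfig
    countries: pd.DataFrame
    cells: pd.DataFrame
    country_shares: pd.DataFrame
    aei: xr.DataArray
    signal: InjectedSignal

    @property
    def cft(self) -> np.ndarray:
        return self.cells[["f_drip", "f_sprinkler", "f_flood"]].to_numpy()


def generate_world(config: WorldConfig,
                   signal: InjectedSignal | None = None) -> World:
    countries = generate_countries(config)
    cells, aei = generate_grid(config, countries)
    shares = generate_country_shares(config, countries)
    return World(config, countries, cells, shares, aei,
                 signal if signal is not None else InjectedSignal())


def _ar1(rng: np.random.Generator, n_time: int, n_cells: int,
         sd: float, rho: float) -> np.ndarray:
    # AR(1) with innovation sd `sd`; stationary sd = sd / sqrt(1 - rho²)
    e = rng.normal(0.0, sd, (n_time, n_cells))
    return lfilter([1.0], [1.0, -rho], e, axis=0)


def _parse_experiment(experiment: str) -> tuple[str, bool]:
    if experiment not in EXPERIMENTS:
        raise InputError(f"unknown experiment {experiment!r}; "
                         f"expected one of {EXPERIMENTS}")
    scen, irr = experiment.split("_")
    return scen, irr == "IRR"


def _aei_for(world: World, scen: str, years: np.ndarray) -> np.ndarray:
    """(n_year, n_cell) irrigated fractions seen by an experiment."""
    if scen == "Hist":
        base = world.aei.sel(scenario="SSP1", year=2010).to_numpy()
        return np.broadcast_to(base, (years.size, base.size)).copy()
    da = world.aei.sel(scenario=scen)
    out = np.empty((years.size, world.config.n_cells))
    for k in range(world.config.n_cells):
        out[:, k] = np.interp(years, da["year"].to_numpy(), da[:, k].to_numpy())
    return out


def generate_climate_cube(world: World, experiment: str, member: int,
                          signal: InjectedSignal | None = None) -> xr.Dataset:
    """3-hourly T2m (°C) and RH (%) cube for one experiment member.

    The weather draw (seasonal + diurnal cycles + AR(1) noise) depends
    only on (seed, scenario, member), so the IRR and NOI cubes of a pair
    are identical except for the injected irrigation signal and its
    noise. SSP cubes carry a linear warming trend, steeper under SSP3.
    """
    config = world.config
    signal = signal if signal is not None else world.signal
    scen, irrigated = _parse_experiment(experiment)
    if not (0 <= member < config.n_ensemble):
        raise InputError(f"member {member} outside 0..{config.n_ensemble - 1}")
    y0, y1 = config.years_hist if scen == "Hist" else config.years_future
    years = np.arange(y0, y1 + 1)
    bpy = config.blocks_per_year
    n_time = years.size * bpy
    n_cells = config.n_cells
    code = _SCEN_CODE[scen]

    hours = np.arange(n_time) * config.timestep_hours
    doy = (hours / 24.0) % 365.0
    hod = hours % 24.0
    year_of_block = np.repeat(years, bpy)
    elapsed_yr = hours / (24.0 * 365.0)

    t_base = world.cells["t_base"].to_numpy()
    rh_base = world.cells["rh_base"].to_numpy()
    seas_t = 8.0 * np.sin(2.0 * np.pi * doy / 365.0)
    diur_t = 4.0 * np.sin(2.0 * np.pi * hod / 24.0 - np.pi / 2.0)
    seas_rh = -8.0 * np.sin(2.0 * np.pi * doy / 365.0)

    rng_w = _rng(config, 10, code, member)
    noise_t = _ar1(rng_w, n_time, n_cells, sd=1.5, rho=0.85)
    noise_rh = _ar1(rng_w, n_time, n_cells, sd=4.0, rho=0.80)

    trend = {"Hist": 0.01, "SSP1": 0.02, "SSP3": 0.05}[scen]
    t2m = (t_base[None, :] + seas_t[:, None] + diur_t[:, None]
           + trend * elapsed_yr[:, None] + noise_t)
    rh = rh_base[None, :] + seas_rh[:, None] + noise_rh

    if irrigated:
        aei_y = _aei_for(world, scen, years)          # (n_year, n_cell)
        aei_block = np.repeat(aei_y, bpy, axis=0)
        rng_s = _rng(config, 20, code, member)
        eps_t = (rng_s.normal(0.0, signal.noise_sd_t, (n_time, n_cells))
                 if signal.noise_sd_t > 0 else 0.0)
        eps_rh = (rng_s.normal(0.0, signal.noise_sd_rh, (n_time, n_cells))
                  if signal.noise_sd_rh > 0 else 0.0)
        t2m = t2m + signal.delta_t * aei_block + eps_t
        rh = rh + signal.delta_rh * aei_block + eps_rh

    rh = np.clip(rh, 0.5, 100.0)

    shape = (n_time, config.nlat, config.nlon)
    ds = xr.Dataset(
        {
            "T2m": (("time", "lat", "lon"),
                    t2m.reshape(shape), {"units": "degC"}),
            "RH": (("time", "lat", "lon"),
                   rh.reshape(shape), {"units": "percent"}),
        },
        coords={
            "time": ("time", hours,
                     {"units": f"hours since {y0}-01-01 00:00",
                      "calendar": "noleap"}),
            "year": ("time", year_of_block),
            "lat": np.arange(config.nlat),
            "lon": np.arange(config.nlon),
        },
        attrs={"experiment": experiment, "member": member,
               "scenario": scen, "irrigated": int(irrigated)},
    )
    return ds


def write_fixture_bundle(world: World, outdir,
                         cubes: dict | None = None) -> Path:
    """Write the world to disk: CSV tables, NetCDF grids, JSON manifest.

    ``cubes`` optionally maps ``(experiment, member)`` to datasets from
    :func:`generate_climate_cube`. The manifest records the seed, the
    injected signal truth and the config, making the bundle reproducible.
    """
    outdir = Path(outdir)
    if not outdir.is_dir():
        raise OSError(f"output directory does not exist: {outdir}")
    world.countries.to_csv(outdir / "countries.csv", index=False)
    world.cells.to_csv(outdir / "cells.csv", index=False)
    world.country_shares.to_csv(outdir / "country_shares.csv", index=False)
    world.aei.to_dataset().to_netcdf(outdir / "aei.nc")
    if cubes:
        for (exp, member), ds in cubes.items():
            ds.to_netcdf(outdir / f"cube_{exp}_m{member}.nc")
    manifest = {
        "seed": world.config.rng_seed,
        "config": dataclasses.asdict(world.config),
        "signal": dataclasses.asdict(world.signal),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir / "manifest.json"


def bundle_checksums(outdir) -> dict[str, str]:
    """SHA-256 of every file in a bundle directory (sorted by name)."""
    out = {}
    for path in sorted(Path(outdir).iterdir()):
        if path.is_file():
            out[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out
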