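"""Dry- and moist-heat exposure diagnostics for factorial experiments.

Dry-heat extremes are 3-hourly blocks whose 2-m air temperature exceeds
the cell's 99th percentile over the pooled historical no-irrigation
(NOI) ensemble; moist-heat extremes apply the same definition to the
wet-bulb temperature Tw, computed with Stull's empirical approximation
from temperature and relative humidity. Exposure is counted in hours per
year, and the effect of a forcing is isolated by differencing paired
experiments (IRR − NOI for irrigation; future − historical for all
forcings; SSP3 − SSP1 for scenario choice), member-wise before ensemble
averaging.
"""

from __future__ import annotations

import numpy as np
import xarray as xr
from scipy.signal import savgol_filter

from .errors import (
    ConfigurationError,
    DomainError,
    EmptySelectionError,
    InputError,
)

HOURS_PER_YEAR = 8760  # 365-day calendar, 2920 3-hourly blocks


def wet_bulb(t2m, rh):
    """Wet-bulb temperature (°C) from T2m (°C) and relative humidity (%).

    Empirical arctangent fit (Stull 2011), valid for humidities above a
    few percent at sea-level pressure:

        Tw = T·atan(0.151977·sqrt(rh + 8.313659)) + atan(T + rh)
             − atan(rh − 1.676331)
             + 0.00391838·rh^{3/2}·atan(0.023101·rh) − 4.68035

    Elementwise over arrays; rh must lie in (0, 100].
    """
    t = np.asarray(t2m, dtype=float)
    phi = np.asarray(rh, dtype=float)
    if np.any(phi <= 0) or np.any(phi > 100):
        raise DomainError("relative humidity must lie in (0, 100] %")
    tw = (
        t * np.arctan(0.151977 * np.sqrt(phi + 8.313659))
        + np.arctan(t + phi)
        - np.arctan(phi - 1.676331)
        + 0.00391838 * phi ** 1.5 * np.arctan(0.023101 * phi)
        - 4.68035
    )
    if isinstance(t2m, xr.DataArray):
        out = t2m.copy(data=np.asarray(tw))
        out.name = "Tw"
        out.attrs = {"units": "degC", "long_name": "wet-bulb temperature"}
        return out
    return tw


def pool_noi(cubes: list[xr.Dataset], var: str) -> xr.DataArray:
    """Concatenate the time axes of an ensemble of cubes for one variable."""
    if not cubes:
        raise InputError("empty cube pool")
    fields = []
    for cube in cubes:
        if var not in cube:
            raise InputError(f"variable {var!r} missing from cube")
        fields.append(cube[var].reset_index("time", drop=True)
                      if "time" in cube[var].indexes else cube[var])
    return xr.concat(fields, dim="time", coords="minimal",
                     compat="override")


def reference_threshold(pooled: xr.DataArray, q: float = 99.0) -> xr.DataArray:
    """Per-cell empirical percentile of a pooled historical sample.

    Linear interpolation between order statistics (numpy's default
    quantile definition). With q = 99 roughly 1 % of the pooled 3-hourly
    blocks exceed the threshold by construction.
    """
    if pooled.sizes.get("time", 0) == 0:
        raise InputError("empty pool")
    thr = pooled.quantile(q / 100.0, dim="time", method="linear")
    thr = thr.drop_vars("quantile")
    thr.name = "threshold"
    thr.attrs["percentile"] = q
    return thr


def exceedance_hours(
    cube: xr.Dataset | xr.DataArray,
    thr: xr.DataArray,
    var: str | None = None,
    timestep_hours: float = 3.0,
) -> xr.DataArray:
    """Hours per year above a per-cell threshold.

    Counts 3-hourly blocks with value strictly above the threshold,
    grouped by the cube's ``year`` coordinate, times the timestep.
    """
    field = cube[var] if isinstance(cube, xr.Dataset) else cube
    for dim in ("lat", "lon"):
        if field.sizes.get(dim) != thr.sizes.get(dim):
            raise InputError("cube and threshold grids do not match")
    if "year" not in field.coords:
        raise InputError("cube lacks a 'year' coordinate on time")
    exceed = (field > thr).groupby("year").sum("time")
    hours = (exceed * timestep_hours).astype(float)
    hours.name = "exceedance_hours"
    hours.attrs["units"] = "hours yr-1"
    return hours


def impact_difference(
    exp_a: xr.DataArray, exp_b: xr.DataArray
) -> xr.DataArray:
    """Member-wise mean-annual exposure difference A − B.

    Both inputs carry dims (member, year, lat, lon); years are averaged
    within each member over its own period, members are paired by index,
    and the result keeps the member dim (reduce with ``.mean('member')``
    for the ensemble-mean impact field).
    """
    if exp_a.sizes.get("member") != exp_b.sizes.get("member"):
        raise InputError("experiments have different ensemble sizes")
    for dim in ("lat", "lon"):
        if exp_a.sizes.get(dim) != exp_b.sizes.get(dim):
            raise InputError("experiments are on different grids")
    a = exp_a.mean("year")
    b = exp_b.mean("year")
    diff = (a.reset_index("member", drop=True)
            if "member" in a.indexes else a) - \
           (b.reset_index("member", drop=True)
            if "member" in b.indexes else b)
    diff.name = "impact"
    diff.attrs["units"] = "hours yr-1"
    return diff


def agreement_mask(member_impacts: xr.DataArray,
                   min_mag: float = 10.0) -> xr.DataArray:
    """Cells where all ensemble members agree on a change of at least
    ``min_mag`` hours per year in the same direction (hatching rule)."""
    if "member" not in member_impacts.dims:
        raise InputError("expected a 'member' dimension")
    pos = (member_impacts >= min_mag).all("member")
    neg = (member_impacts <= -min_mag).all("member")
    mask = pos | neg
    mask.name = "agreement"
    return mask


def classify_hotspots(aei_hist: xr.DataArray, aei_future: xr.DataArray,
                      thresh: float = 0.2) -> xr.DataArray:
    """Irrigation hotspot categories per cell.

    ``traditional``: more than ``thresh`` of the cell irrigated
    historically; ``new``: at most ``thresh`` historically but above it
    by the future reference year (2070); ``none`` otherwise.
    """
    for f in (aei_hist, aei_future):
        vals = np.asarray(f)
        if np.any(vals < 0) or np.any(vals > 1):
            raise InputError("AEI fractions must lie in [0, 1]")
    traditional = aei_hist > thresh
    new = (~traditional) & (aei_future > thresh)
    cat = xr.where(traditional, "traditional", xr.where(new, "new", "none"))
    cat.name = "hotspot"
    return cat


def area_mean(field: xr.DataArray, mask: xr.DataArray,
              areas: xr.DataArray) -> xr.DataArray:
    """Area-weighted mean of ``field`` over masked cells.

    Reduces the spatial dims; leading dims (year, member, ...) survive,
    giving e.g. a regional annual time series.
    """
    mask = mask.astype(bool)
    if not bool(mask.any()):
        raise EmptySelectionError("mask selects no grid cells")
    w = areas.where(mask, 0.0)
    spatial = [d for d in ("lat", "lon", "cell") if d in field.dims]
    return (field * w).sum(spatial) / w.sum(spatial)


def aggregate_iww(depth_mm: xr.DataArray, areas_km2: xr.DataArray,
                  mask: xr.DataArray | None = None):
    """Irrigation water withdrawal volume (km³ yr⁻¹) over a region.

    ``depth_mm`` is the withdrawal depth over the *full* cell area in
    mm yr⁻¹; volume is Σ depth × area × 10⁻⁶.
    """
    if np.any(np.asarray(depth_mm) < 0):
        raise InputError("negative withdrawal depth")
    if mask is not None:
        depth_mm = depth_mm.where(mask.astype(bool), 0.0)
    vol = (depth_mm * areas_km2 * 1e-6)
    spatial = [d for d in ("lat", "lon", "cell") if d in vol.dims]
    out = vol.sum(spatial)
    return float(out) if out.ndim == 0 else out


def savgol_smooth(series, order: int = 2, window: int = 7) -> np.ndarray:
    """Savitzky–Golay smoothing of an annual series.

    Local least-squares polynomial of the given order over an odd,
    centred window. Endpoints are handled by scipy's ``interp`` mode: a
    single polynomial is fitted to the last full window and evaluated
    over the edge points, so series no longer than the window are
    reproduced only up to that fit.
    """
    series = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ConfigurationError("window must be odd")
    if window > series.size:
        raise ConfigurationError("window longer than the series")
    if order >= window:
        raise ConfigurationError("polynomial order must be below the window")
    return savgol_filter(series, window_length=window, polyorder=order,
                         mode="interp")
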