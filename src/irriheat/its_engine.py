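"""Transient gridded irrigation-technique shares (ITS).

Each grid cell's irrigated area is split between drip, sprinkler and
flood irrigation (paddy is folded into flood). Shares live on the
2-simplex and are constrained by the cell's crop-functional-type (CFT)
composition: drip irrigation can only be applied on drip-suitable CFTs,
sprinkler on drip- plus sprinkler-suitable CFTs, so

    drip <= f_drip,   sprinkler <= f_drip + f_sprinkler - drip,
    flood >= f_flood.

The transition mechanism: every 5-year window the flood share drops by
``rate`` percentage points per year (from `transition_drivers`), the
reduction being redistributed to drip and sprinkler in proportion to the
drip/sprinkler CFT fractions, subject to the suitability caps. 5-year
node values are interpolated linearly to annual resolution.

All operations are vectorised: a shares (or CFT) argument is an array
whose last axis has length 3 in the order (drip, sprinkler, flood).
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .errors import ConfigurationError, ConsistencyError, NoHeadroomError

DRIP, SPRINKLER, FLOOD = 0, 1, 2
TECH_NAMES = ("drip", "sprinkler", "flood")

_ATOL = 1e-9


def _as_simplex(arr, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape[-1] != 3:
        raise ConsistencyError(f"{name}: last axis must have length 3")
    if np.any(arr < -_ATOL) or np.any(arr > 1 + _ATOL):
        raise ConsistencyError(f"{name}: fractions outside [0, 1]")
    if np.any(np.abs(arr.sum(axis=-1) - 1.0) > 1e-6):
        raise ConsistencyError(f"{name}: fractions do not sum to 1")
    return arr


def validate_shares(shares, cft=None) -> np.ndarray:
    """Check the simplex constraint and, given a CFT composition, the
    suitability caps. Returns the shares as a float array."""
    shares = _as_simplex(shares, "shares")
    if cft is not None:
        cft = _as_simplex(cft, "cft")
        if np.any(shares[..., DRIP] > cft[..., DRIP] + 1e-6):
            raise ConsistencyError("drip share exceeds drip-CFT fraction")
        sprink_cap = cft[..., DRIP] + cft[..., SPRINKLER] - shares[..., DRIP]
        if np.any(shares[..., SPRINKLER] > sprink_cap + 1e-6):
            raise ConsistencyError("sprinkler share exceeds suitability cap")
    return shares


def baseline_assign(country_shares, cft) -> np.ndarray:
    """Downscale country technique shares to a cell, by priority.

    Drip irrigation is assigned first, onto drip-suitable CFTs only;
    sprinkler irrigation next, onto sprinkler CFTs with any excess
    spilling over to remaining drip CFTs; flood irrigation covers
    whatever irrigated cropland is left. Country-level drip demand beyond
    the cell's drip-CFT fraction is demoted to sprinkler (then flood).
    """
    country_shares = _as_simplex(country_shares, "country_shares")
    cft = _as_simplex(cft, "cft")
    d_req = country_shares[..., DRIP]
    s_req = country_shares[..., SPRINKLER]
    f_d, f_s = cft[..., DRIP], cft[..., SPRINKLER]

    drip = np.minimum(d_req, f_d)
    # demoted drip demand joins the sprinkler request
    s_req = s_req + (d_req - drip)
    sprinkler = np.minimum(s_req, f_d + f_s - drip)
    flood = 1.0 - drip - sprinkler
    return np.stack([drip, sprinkler, flood], axis=-1)


def redistribution_weights(cft):
    """Split of a flood-share decrement between drip and sprinkler.

    Proportional to the drip/sprinkler CFT fractions:
    ``w_drip = f_drip / (f_drip + f_sprinkler)`` and complementarily for
    sprinkler. For scalar input with no drip/sprinkler CFTs at all the
    flood share cannot decrease and ``NoHeadroomError`` is raised; in
    array input such cells get weights (0, 0) and a zero decrement
    applies there anyway (their flood floor is 1).
    """
    cft = _as_simplex(cft, "cft")
    denom = cft[..., DRIP] + cft[..., SPRINKLER]
    if cft.ndim == 1:
        if denom == 0:
            raise NoHeadroomError(
                "no drip- or sprinkler-suitable CFTs: flood cannot decrease"
            )
        return float(cft[DRIP] / denom), float(cft[SPRINKLER] / denom)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_d = np.where(denom > 0, cft[..., DRIP] / np.where(denom > 0, denom, 1), 0.0)
        w_s = np.where(denom > 0, cft[..., SPRINKLER] / np.where(denom > 0, denom, 1), 0.0)
    return w_d, w_s


def step_shares(shares, cft, rate, n_years) -> np.ndarray:
    """Advance technique shares by one multi-year window.

    The flood share drops by ``rate`` percentage points per year
    (absolute decrement of the share) for ``n_years`` years, limited by
    the flood floor ``f_flood``. The decrement is split between drip and
    sprinkler by `redistribution_weights`; if the drip increment would
    push drip past its CFT cap the excess is reassigned to sprinkler.
    (The sprinkler cap cannot bind on its own while the flood floor
    holds, since drip + sprinkler <= 1 - f_flood = f_drip + f_sprinkler.)
    """
    shares = validate_shares(shares, cft)
    cft = np.asarray(cft, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ConsistencyError("rate must be non-negative")

    flood = shares[..., FLOOD]
    headroom = np.maximum(flood - cft[..., FLOOD], 0.0)
    delta = np.minimum(rate * n_years / 100.0, headroom)

    # weights computed inline so that zero-headroom cells (all-flood CFTs,
    # where delta is necessarily 0) pass through instead of raising
    denom = cft[..., DRIP] + cft[..., SPRINKLER]
    safe = np.where(denom > 0, denom, 1.0)
    w_d = np.where(denom > 0, cft[..., DRIP] / safe, 0.0)
    drip_inc = np.minimum(delta * w_d,
                          cft[..., DRIP] - shares[..., DRIP])
    sprink_inc = delta - drip_inc
    drip = shares[..., DRIP] + drip_inc
    sprinkler = shares[..., SPRINKLER] + sprink_inc
    out = np.stack([drip, sprinkler, 1.0 - drip - sprinkler], axis=-1)
    return validate_shares(out, cft)


def build_transient_its(
    baseline,
    rates,
    cft,
    years: tuple[int, int],
    cell_country=None,
    base_year: int = 2010,
) -> xr.DataArray:
    """Annual per-cell technique shares from a 2010 baseline.

    Parameters
    ----------
    baseline : (n_cell, 3) array
        Cell shares at ``base_year`` (from `baseline_assign`).
    rates : mapping or DataFrame
        Annual rates per 5-year window. Either a DataFrame with columns
        country/year/rate (requires ``cell_country``) or a mapping
        ``{window_start_year: rate}`` applied uniformly.
    cft : (n_cell, 3) array
        CFT composition, held fixed over the projection.
    years : (start, end) inclusive annual output range.

    Node values at 5-year steps are computed by successive `step_shares`;
    annual values are linear interpolations between nodes (node years are
    reproduced exactly).
    """
    baseline = validate_shares(baseline, cft)
    y0, y1 = years
    if y0 < base_year:
        raise ConfigurationError("output range starts before the baseline year")
    n_cell = baseline.shape[0]

    node_years = list(range(base_year, y1 + 5, 5))
    if node_years[-1] < y1:
        node_years.append(node_years[-1] + 5)

    def window_rate(year):
        if hasattr(rates, "columns"):
            sub = rates[rates["year"] == year]
            if cell_country is None:
                raise ConfigurationError("per-country rates need cell_country")
            lookup = dict(zip(sub["country"], sub["rate"]))
            try:
                return np.array([lookup[c] for c in cell_country])
            except KeyError as e:
                raise ConfigurationError(
                    f"missing rate for country {e} in window {year}"
                ) from None
        try:
            return np.full(n_cell, float(rates[year]))
        except KeyError:
            raise ConfigurationError(f"missing rate window {year}") from None

    nodes = [baseline]
    for year in node_years[:-1]:
        nodes.append(step_shares(nodes[-1], cft, window_rate(year), 5))
    node_arr = np.stack(nodes)  # (n_node, n_cell, 3)

    annual_years = np.arange(y0, y1 + 1)
    out = np.empty((annual_years.size, n_cell, 3))
    for k in range(3):
        for c in range(n_cell):
            out[:, c, k] = np.interp(annual_years, node_years, node_arr[:, c, k])
    da = xr.DataArray(
        out,
        dims=("year", "cell", "technique"),
        coords={"year": annual_years, "cell": np.arange(n_cell),
                "technique": list(TECH_NAMES)},
        name="its",
    )
    da.attrs["base_year"] = base_year
    return da


def distribute_to_cfts(shares, cft) -> np.ndarray:
    """Within-CFT-class technique fractions implied by cell shares.

    Returns a (..., 3, 3) array ``M`` where ``M[..., i, j]`` is the
    fraction of CFT class ``i`` (drip-suitable, sprinkler-suitable,
    flood-only) irrigated with technique ``j``. Follows the
    `baseline_assign` priority: drip fills drip CFTs, sprinkler fills
    sprinkler CFTs and spills over to drip CFTs, flood covers the rest.
    The CFT-fraction-weighted column sums reproduce the cell shares.
    """
    shares = validate_shares(shares, cft)
    cft = _as_simplex(cft, "cft")
    d, s = shares[..., DRIP], shares[..., SPRINKLER]
    f_d, f_s = cft[..., DRIP], cft[..., SPRINKLER]

    sprink_on_sprink = np.minimum(s, f_s)
    spill = s - sprink_on_sprink  # sprinkler onto drip CFTs

    def frac(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)

    M = np.zeros(shares.shape[:-1] + (3, 3))
    M[..., 0, DRIP] = frac(d, f_d)
    M[..., 0, SPRINKLER] = frac(spill, f_d)
    M[..., 0, FLOOD] = np.where(f_d > 0, 1.0, 0.0) - M[..., 0, DRIP] - M[..., 0, SPRINKLER]
    M[..., 1, SPRINKLER] = frac(sprink_on_sprink, f_s)
    M[..., 1, FLOOD] = np.where(f_s > 0, 1.0, 0.0) - M[..., 1, SPRINKLER]
    M[..., 2, FLOOD] = np.where(cft[..., FLOOD] > 0, 1.0, 0.0)

    if np.any(M < -1e-9):
        raise ConsistencyError("shares infeasible under the CFT caps")
    recon = np.einsum("...i,...ij->...j", cft, M)
    if np.any(np.abs(recon - shares) > 1e-9):
        raise ConsistencyError("per-class assignment fails to reconstruct shares")
    return M
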