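"""Source-apportioned PM2.5 exposure assessment.

Turns paired chemical-transport-model (CTM) runs — one with and one
without open-fire emissions — plus an annual satellite-based PM2.5
reference into calibrated total, fire and non-fire PM2.5 series:

* fire fraction  rho = (PM_wfire - PM_nofire) / PM_wfire, clamped to [0, 1];
* annual calibration rate  eta = PM_satellite / mean_month(PM_wfire);
* decomposition  total = eta * PM_wfire, fire = eta * rho * PM_wfire,
  non-fire = eta * (1 - rho) * PM_wfire.

Coarse CTM rasters are downscaled to a fine grid with inverse-distance
weighting (k = 4 nearest centres, power 2, great-circle distance) before
calibration, matching the order in which the satellite reference is
defined on the fine grid.  Gestational exposure is the arithmetic mean
over the inclusive window from the conception month to the termination
month.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
from scipy.spatial import cKDTree

__all__ = [
    "fire_fraction",
    "calibration_rate",
    "decompose",
    "idw_downscale",
    "downscale_stack",
    "calibrate_stack",
    "window_mean",
    "ExposureSeries",
    "extract_at_points",
    "MONTHLY_VARS",
    "write_fields",
    "read_fields",
]

EARTH_RADIUS_KM = 6371.0

#: monthly variables carried through downscaling and extraction
MONTHLY_VARS = (
    "pm_wfire",
    "pm_nofire",
    "burned_frac",
    "dry_matter",
    "temperature",
    "humidity",
)

_CLAMP_LOG: dict = {"n_clamped": 0}


def fire_fraction(pm_wfire, pm_nofire):
    """Monthly fractional fire contribution to simulated PM2.5.

    ``(wfire - nofire) / wfire`` clamped into [0, 1].  CTM chemistry is
    nonlinear, so the without-fire run can occasionally exceed the
    with-fire run; a negative fire concentration is physically
    uninterpretable, hence the clamp (occurrences are counted).  Cells
    with ``wfire == 0`` return 0.
    """
    w = np.asarray(pm_wfire, dtype=float)
    n = np.asarray(pm_nofire, dtype=float)
    if np.any(w < 0) or np.any(n < 0):
        raise ValueError("PM2.5 concentrations must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        rho = np.where(w > 0, (w - n) / np.where(w > 0, w, 1.0), 0.0)
    n_clamped = int(np.sum((rho < 0) | (rho > 1)))
    if n_clamped:
        _CLAMP_LOG["n_clamped"] += n_clamped
    rho = np.clip(rho, 0.0, 1.0)
    return rho if rho.ndim else float(rho)


def calibration_rate(pm_satellite_annual, monthly_wfire, axis: int = -1):
    """Annual calibration rate eta = satellite / mean of 12 monthly values.

    ``monthly_wfire`` must supply exactly 12 monthly with-fire values per
    year along ``axis``; an all-zero year leaves the rate undefined.
    """
    m = np.asarray(monthly_wfire, dtype=float)
    if m.shape[axis] != 12:
        raise ValueError("calibration needs exactly 12 monthly values per year")
    denom = m.mean(axis=axis)
    if np.any(denom <= 0):
        raise ValueError("all-zero monthly PM2.5: calibration rate undefined")
    eta = np.asarray(pm_satellite_annual, dtype=float) / denom
    return eta if np.ndim(eta) else float(eta)


def decompose(pm_wfire, rho, eta):
    """Calibrated (total, fire, non-fire) PM2.5 from Eq-style identities."""
    w = np.asarray(pm_wfire, dtype=float)
    r = np.asarray(rho, dtype=float)
    e = np.asarray(eta, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("fire fraction must lie in [0, 1]")
    if np.any(e <= 0):
        raise ValueError("calibration rate must be positive")
    total = e * w
    fire = e * r * w
    nonfire = total - fire  # exact additivity by construction
    return total, fire, nonfire


# ----------------------------------------------------------------------
def _sphere_xyz(lat_deg, lon_deg):
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    return np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def idw_weights(coarse_lat, coarse_lon, fine_lat, fine_lon, k: int = 4, power: float = 2.0):
    """Neighbour indices and IDW weights from coarse centres to fine centres.

    Nearest neighbours are found on the unit sphere (chord distance is
    monotone in great-circle distance, so the ordering is exact); the
    weights use the great-circle distance itself.  A fine centre that
    coincides with a coarse centre receives that cell's value exactly.
    """
    clat, clon = np.meshgrid(coarse_lat, coarse_lon, indexing="ij")
    cpts = _sphere_xyz(clat.ravel(), clon.ravel())
    if cpts.shape[0] == 0:
        raise ValueError("empty coarse field")
    flat, flon = np.meshgrid(fine_lat, fine_lon, indexing="ij")
    fpts = _sphere_xyz(flat.ravel(), flon.ravel())
    k = min(k, cpts.shape[0])
    tree = cKDTree(cpts)
    chord, idx = tree.query(fpts, k=k)
    if k == 1:  # scipy drops the neighbour axis for k=1
        chord = chord[:, None]
        idx = idx[:, None]
    gc = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
    exact = gc[:, 0] < 1e-9
    with np.errstate(divide="ignore"):
        w = 1.0 / np.where(gc > 0, gc, np.inf) ** power
    w[exact] = 0.0
    w[exact, 0] = 1.0
    w /= w.sum(axis=1, keepdims=True)
    return idx, w


def idw_downscale(field, coarse_lat, coarse_lon, fine_lat, fine_lon, k: int = 4, power: float = 2.0):
    """Downscale ``field`` (..., nlat, nlon) onto the fine lat/lon axes.

    IDW is a convex combination, so the result stays within the coarse
    field's min/max bounds.
    """
    field = np.asarray(field, dtype=float)
    nlat, nlon = len(coarse_lat), len(coarse_lon)
    if field.shape[-2:] != (nlat, nlon):
        raise ValueError("field shape does not match coarse axes")
    idx, w = idw_weights(coarse_lat, coarse_lon, fine_lat, fine_lon, k=k, power=power)
    flat = field.reshape(field.shape[:-2] + (nlat * nlon,))
    vals = flat[..., idx]  # (..., nfine, k)
    out = (vals * w).sum(axis=-1)
    return out.reshape(field.shape[:-2] + (len(fine_lat), len(fine_lon)))


def fine_axes(lat_min, lat_max, lon_min, lon_max, res: float = 0.1):
    """Fine-grid cell centres: multiples of ``res`` offset by ``res/2``."""
    lat0 = np.floor(lat_min / res) * res + res / 2
    lon0 = np.floor(lon_min / res) * res + res / 2
    lats = np.arange(lat0, lat_max, res)
    lons = np.arange(lon0, lon_max, res)
    return np.round(lats, 6), np.round(lons, 6)


def downscale_stack(stack: xr.Dataset, fine_lat, fine_lon, k: int = 4, power: float = 2.0) -> xr.Dataset:
    """Downscale all monthly CTM variables plus the fire fraction.

    The with-fire and without-fire runs and their fire fraction rho are
    each interpolated to the fine grid (rho is downscaled as its own
    field rather than recomputed from the downscaled runs, matching the
    order of operations in the calibration workflow); the auxiliary
    indicator and weather fields ride along with the same weights.
    """
    clat = stack["lat"].values
    clon = stack["lon"].values
    idx, w = idw_weights(clat, clon, fine_lat, fine_lon, k=k, power=power)
    nlat, nlon = len(fine_lat), len(fine_lon)

    def _apply(arr):
        flat = arr.reshape(arr.shape[:-2] + (-1,))
        out = (flat[..., idx] * w).sum(axis=-1)
        return out.reshape(arr.shape[:-2] + (nlat, nlon))

    data = {}
    for var in MONTHLY_VARS:
        data[var] = (("month", "lat", "lon"), _apply(stack[var].values))
    rho = fire_fraction(stack["pm_wfire"].values, stack["pm_nofire"].values)
    data["rho"] = (("month", "lat", "lon"), _apply(rho))
    coords = {"month": stack["month"].values, "lat": fine_lat, "lon": fine_lon}
    out = xr.Dataset(data, coords=coords)
    if "year" in stack.coords:
        out = out.assign_coords(year=stack["year"].values)
    return out


def calibrate_stack(fine: xr.Dataset, satellite: xr.DataArray) -> xr.Dataset:
    """Calibrate downscaled fields against the annual satellite reference.

    ``satellite`` has dims (year, lat, lon) on the same fine grid.  The
    calibration rate eta is computed per cell and year and held constant
    across the year's months; total/fire/non-fire are then derived so
    that the annual mean of the calibrated total equals the satellite
    reference exactly.
    """
    months = fine["month"].values
    years = satellite["year"].values
    if len(months) != 12 * len(years):
        raise ValueError("calibration requires complete years of monthly data")
    wf = fine["pm_wfire"].values.reshape(len(years), 12, *fine["pm_wfire"].shape[1:])
    eta_y = calibration_rate(satellite.values, wf, axis=1)  # (year, lat, lon)
    eta_m = np.repeat(eta_y, 12, axis=0)
    rho = fine["rho"].values
    total, fire, nonfire = decompose(fine["pm_wfire"].values, rho, eta_m)
    out = fine.copy()
    out["eta"] = (("year", "lat", "lon"), eta_y)
    out["total"] = (("month", "lat", "lon"), total)
    out["fire"] = (("month", "lat", "lon"), fire)
    out["nonfire"] = (("month", "lat", "lon"), nonfire)
    out["pm_satellite"] = satellite
    out = out.assign_coords(year=years)
    return out


# ----------------------------------------------------------------------
def window_mean(series, months, conception: int, gestation: int) -> float:
    """Mean of a monthly series over [conception, conception+gestation-1].

    ``months`` are consecutive century-month codes.  Raises if any window
    month is missing from the series (such events are exposure-invalid
    and excluded downstream).
    """
    months = np.asarray(months)
    if gestation < 1:
        raise ValueError("gestation must be at least one month")
    s = conception - int(months[0])
    e = s + gestation
    if s < 0 or e > months.size:
        raise KeyError("exposure window extends outside the available months")
    return float(np.asarray(series, dtype=float)[s:e].mean())


@dataclass
class ExposureSeries:
    """Monthly exposure series at a set of points (fine-grid cells).

    ``data[var]`` has shape (n_points, n_months); ``months`` are
    consecutive century-month codes.  Window means are computed with a
    cumulative-sum so that whole event tables are averaged at once.
    """

    months: np.ndarray
    data: dict
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self):
        self.months = np.asarray(self.months, dtype=int)
        if np.any(np.diff(self.months) != 1):
            raise ValueError("months must be consecutive century-month codes")
        self._csum = {
            v: np.concatenate(
                [np.zeros((a.shape[0], 1)), np.cumsum(a, axis=1)], axis=1
            )
            for v, a in self.data.items()
        }

    @property
    def variables(self):
        return list(self.data)

    def window_means(self, var: str, point_idx, conception, gestation):
        """Vectorised window means; returns ``(values, valid)``.

        Events whose window is not fully covered get NaN and
        ``valid=False`` (exposure-invalid, to be excluded downstream).
        """
        cs = self._csum[var]
        p = np.asarray(point_idx, dtype=int)
        c = np.asarray(conception, dtype=int)
        g = np.asarray(gestation, dtype=int)
        s = c - self.months[0]
        e = s + g
        valid = (s >= 0) & (e <= self.months.size) & (g >= 1)
        s_safe = np.clip(s, 0, self.months.size)
        e_safe = np.clip(e, 0, self.months.size)
        vals = (cs[p, e_safe] - cs[p, s_safe]) / np.maximum(g, 1)
        return np.where(valid, vals, np.nan), valid

    def to_frame(self, point_ids=None) -> pd.DataFrame:
        """Long table: one row per (point, month), one column per variable."""
        npts = len(self.lat)
        ids = np.arange(npts) if point_ids is None else np.asarray(point_ids)
        rows = {
            "point_id": np.repeat(ids, self.months.size),
            "month_cmc": np.tile(self.months, npts),
        }
        for v, a in self.data.items():
            rows[v] = a.ravel()
        return pd.DataFrame(rows)


def point_cell_index(lats, lons, grid_lat, grid_lon):
    """Map points to fine-grid cells by containment (lower edge inclusive)."""
    grid_lat = np.asarray(grid_lat)
    grid_lon = np.asarray(grid_lon)
    res_lat = grid_lat[1] - grid_lat[0] if grid_lat.size > 1 else 1.0
    res_lon = grid_lon[1] - grid_lon[0] if grid_lon.size > 1 else 1.0
    i = np.floor((np.asarray(lats) - (grid_lat[0] - res_lat / 2)) / res_lat).astype(int)
    j = np.floor((np.asarray(lons) - (grid_lon[0] - res_lon / 2)) / res_lon).astype(int)
    if np.any((i < 0) | (i >= grid_lat.size) | (j < 0) | (j >= grid_lon.size)):
        raise ValueError("point outside the field extent")
    return i, j


def extract_at_points(calibrated: xr.Dataset, lats, lons) -> ExposureSeries:
    """Monthly exposure series at point locations from a calibrated stack."""
    i, j = point_cell_index(lats, lons, calibrated["lat"].values, calibrated["lon"].values)
    variables = ("total", "fire", "nonfire") + tuple(
        v for v in MONTHLY_VARS if v not in ("pm_wfire", "pm_nofire")
    )
    data = {v: calibrated[v].values[:, i, j].T.copy() for v in variables}
    return ExposureSeries(
        months=calibrated["month"].values,
        data=data,
        lat=np.asarray(lats, dtype=float),
        lon=np.asarray(lons, dtype=float),
    )


def exposure_table(series: ExposureSeries, mother_ids) -> pd.DataFrame:
    """Per-mother monthly exposure CSV schema (one row per mother-month)."""
    df = series.to_frame(point_ids=mother_ids)
    return df.rename(columns={"point_id": "mother_id"})


# ----------------------------------------------------------------------
def write_fields(stack: xr.Dataset, path) -> None:
    """Write a field stack to NetCDF (scipy backend, netCDF3)."""
    enc = stack.copy()
    enc.attrs.setdefault("time_convention", "months since 1900-01 (century-month code)")
    enc.to_netcdf(path, engine="scipy")


def read_fields(path) -> xr.Dataset:
    ds = xr.open_dataset(path, engine="scipy")
    return ds.load()
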