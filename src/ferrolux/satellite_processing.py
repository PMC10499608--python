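"""Satellite-side processing of gridded fluorescence, chlorophyll and SST.

Gridded variables are carried as :class:`xarray.DataArray` objects with
``(time, lat, lon)`` axes (``GriddedField`` in the package's vocabulary);
missing data are NaN.  The chain implemented here mirrors the standard
level-3 treatment of the MODIS-Aqua fluorescence product:

1. nFLH (normalized fluorescence line height) is *denormalized* back to
   FLH by multiplying with the cosine of the solar zenith angle at each
   pixel latitude for the composite's mid-time point — valid where the
   passive fluorescence signal is on its light-saturated plateau at
   overpass irradiances.
2. Pixels with chlorophyll a outside the validated 0.1–0.4 mg m⁻³ window
   are excluded (below: FLH detection limit; above: non-linear
   chlorophyll–absorption relation).
3. FLH is divided by chlorophyll a to give the satellite passive
   fluorescence yield F/Chl_sat.
4. Regional (latitude-weighted) monthly series and anomalies (value
   minus record average) feed the regression stage.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .stats_core import InvalidInputError

__all__ = [
    "solar_declination",
    "solar_zenith",
    "denormalize_nflh",
    "mask_chl",
    "fchl_sat",
    "region_series",
    "anomalies",
    "track_average",
    "NINO3_BOX",
    "NINO3_CORE_BOX",
]

# standard Niño3 definition: 5°S–5°N, 150°W–90°W
NINO3_BOX = (-5.0, 5.0, -150.0, -90.0)
# narrower equatorial band capturing the upwelling core
NINO3_CORE_BOX = (-1.5, 1.5, -150.0, -90.0)

EARTH_RADIUS_KM = 6371.0


def solar_declination(day_of_year) -> np.ndarray:
    """Solar declination (degrees) from the Spencer Fourier series."""
    g = 2.0 * np.pi * (np.asarray(day_of_year, dtype=float) - 1.0) / 365.0
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    return np.degrees(decl)


def solar_zenith(lat, date, local_solar_time: float) -> np.ndarray:
    """Solar zenith angle (degrees) at given latitude and local solar time.

    Uses the day-of-year declination approximation and the hour angle
    ``15° × (local_solar_time − 12)``.  Intended for the low- and
    mid-latitude domain (|lat| ≤ 66°); higher latitudes are computed but
    flagged with a warning.

    Parameters
    ----------
    lat : degrees north (scalar or array)
    date : anything ``pandas.Timestamp`` accepts
    local_solar_time : hours (12 = solar noon)
    """
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 66.0):
        warnings.warn(
            "solar_zenith outside validated |lat| <= 66 deg domain",
            stacklevel=2,
        )
    doy = pd.Timestamp(date).dayofyear
    decl = np.radians(solar_declination(doy))
    hour_angle = np.radians(15.0 * (local_solar_time - 12.0))
    latr = np.radians(lat)
    cosz = np.sin(latr) * np.sin(decl) + np.cos(latr) * np.cos(decl) * np.cos(
        hour_angle
    )
    return np.degrees(np.arccos(np.clip(cosz, -1.0, 1.0)))


def denormalize_nflh(
    nflh: xr.DataArray, overpass_local_time: float = 13.5
) -> xr.DataArray:
    """Convert nFLH to FLH by multiplying with cos(solar zenith angle).

    The zenith angle is evaluated at each pixel latitude for the
    composite's mid-time point (the value on the ``time`` axis) at the
    sensor's local overpass hour.  Pixels with the sun at or below the
    horizon (SZA ≥ 90°) are masked.
    """
    if "time" not in nflh.dims:
        raise InvalidInputError("nflh needs a time axis of composite mid-points")
    cosz = np.empty((nflh.sizes["time"], nflh.sizes["lat"]))
    for i, t in enumerate(pd.DatetimeIndex(nflh["time"].values)):
        sza = solar_zenith(nflh["lat"].values, t, overpass_local_time)
        cz = np.cos(np.radians(sza))
        cz[sza >= 90.0] = np.nan
        cosz[i] = cz
    cosz_da = xr.DataArray(
        cosz, coords={"time": nflh["time"], "lat": nflh["lat"]},
        dims=("time", "lat"),
    )
    flh = nflh * cosz_da
    flh.name = "flh"
    flh.attrs.update(nflh.attrs)
    flh.attrs["long_name"] = "fluorescence line height (denormalized)"
    return flh


def mask_chl(
    chl: xr.DataArray, lo: float = 0.1, hi: float = 0.4
) -> xr.DataArray:
    """Validity mask keeping ``lo <= chl <= hi`` (boundaries retained).

    Exclusion thresholds are strict inequalities: pixels are dropped only
    when chlorophyll is strictly below ``lo`` or strictly above ``hi``.
    """
    keep = (chl >= lo) & (chl <= hi) & chl.notnull()
    keep.name = "chl_mask"
    return keep


def fchl_sat(
    flh: xr.DataArray, chl: xr.DataArray, mask: xr.DataArray | None = None
) -> xr.DataArray:
    """Satellite passive fluorescence yield: FLH / chlorophyll a."""
    if mask is None:
        mask = mask_chl(chl)
    out = (flh / chl.where(chl > 0)).where(mask)
    out.name = "fchl_sat"
    out.attrs["units"] = "W m-2 sr-1 um-1 (mg Chl m-3)-1"
    return out


def region_series(
    field: xr.DataArray,
    box: tuple[float, float, float, float] = NINO3_BOX,
    min_valid_frac: float = 0.2,
) -> pd.DataFrame:
    """Latitude-weighted monthly area mean of a field over a lat/lon box.

    Parameters
    ----------
    box : (lat_min, lat_max, lon_min, lon_max), bounds inclusive.
    min_valid_frac : months with a smaller fraction of unmasked pixels
        are flagged (``valid`` column False) and their value set to NaN.

    Returns a DataFrame indexed by time with columns ``value``,
    ``valid_frac`` and ``valid``.
    """
    lat_min, lat_max, lon_min, lon_max = box
    sub = field.where(
        (field["lat"] >= lat_min) & (field["lat"] <= lat_max)
        & (field["lon"] >= lon_min) & (field["lon"] <= lon_max),
        drop=True,
    )
    if sub.sizes.get("lat", 0) == 0 or sub.sizes.get("lon", 0) == 0:
        raise InvalidInputError(f"box {box} contains no grid cells")
    w = np.cos(np.radians(sub["lat"]))
    weighted = sub.weighted(w)
    value = weighted.mean(dim=("lat", "lon"), skipna=True)
    valid_frac = sub.notnull().mean(dim=("lat", "lon"))
    df = pd.DataFrame(
        {
            "value": np.atleast_1d(value.values),
            "valid_frac": np.atleast_1d(valid_frac.values),
        },
        index=pd.DatetimeIndex(np.atleast_1d(sub["time"].values), name="time")
        if "time" in sub.dims
        else [0],
    )
    df["valid"] = df["valid_frac"] >= min_valid_frac
    df.loc[~df["valid"], "value"] = np.nan
    return df


def anomalies(series, mode: str = "record"):
    """Anomalies of a time series: value minus the record average.

    ``mode='record'`` subtracts the full-record mean (the literal
    definition used for the Niño3 series); ``mode='climatology'``
    subtracts the per-calendar-month mean, removing the seasonal cycle.
    """
    if isinstance(series, pd.DataFrame):
        out = series.copy()
        out["value"] = anomalies(series["value"], mode=mode)
        return out
    s = pd.Series(series).astype(float)
    if mode == "record":
        return s - s.mean()
    if mode == "climatology":
        idx = pd.DatetimeIndex(s.index)
        return s - s.groupby(idx.month).transform("mean")
    raise InvalidInputError(f"unknown anomaly mode {mode!r}")


def _haversine_km(lat1, lon1, lat2, lon2):
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def track_average(
    field: xr.DataArray, points, radius_km: float = 100.0
) -> np.ndarray:
    """Mean of unmasked pixels within ``radius_km`` of each track point.

    ``field`` is a 2-D (lat, lon) array — e.g. a climatological mean —
    and ``points`` an iterable of (lat, lon).  Points with no unmasked
    pixel inside the circle yield NaN.
    """
    if "time" in field.dims:
        field = field.mean(dim="time", skipna=True)
    lat2d, lon2d = xr.broadcast(field["lat"], field["lon"])
    lat2d = lat2d.values
    lon2d = lon2d.values
    vals = field.values
    out = []
    for plat, plon in points:
        d = _haversine_km(plat, plon, lat2d, lon2d)
        sel = (d <= radius_km) & np.isfinite(vals)
        out.append(float(np.mean(vals[sel])) if sel.any() else np.nan)
    return np.asarray(out)
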