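"""Shipboard above-water hyperspectral radiometry reductions.

Turns per-timestamp water-leaving radiance spectra into:

* fluorescence line height (FLH) — the height of the ~678 nm chlorophyll
  fluorescence peak above a linear baseline interpolated between the
  667 nm and 748 nm bands,

      FLH = L678 − L667 − (L748 − L667) · (678 − 667) / (748 − 667),

* OC3 maximum-band-ratio chlorophyll a from remote-sensing reflectance,
* the shipboard passive fluorescence yield F/Chl = FLH / Chl,
* a midday (12:00–15:00 local solar time) extraction matching the
  satellite overpass window, and
* a PAR-binned saturating light-response fit of F/Chl.

Band radiances are the mean of spectral samples within ±2 nm of each
nominal centre, falling back to linear interpolation between adjacent
grid points when no sample lands in the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import (
    InvalidInputError,
    TanhFitResults,
    fit_tanh_response,
    rma_regression,
    rolling_mean,
)

__all__ = [
    "Spectrum",
    "OC3Coefficients",
    "OC3_MODIS_DEFAULT",
    "FLH_BANDS",
    "band_value",
    "compute_flh",
    "compute_oc3_chl",
    "build_yield_series",
    "midday_extract",
    "par_response",
    "local_solar_time",
]

FLH_BANDS = (667.0, 678.0, 748.0)


@dataclass
class Spectrum:
    """One above-water hyperspectral record.

    ``wavelengths`` (nm, strictly increasing) with water-leaving radiance
    ``l_w`` (W m⁻² sr⁻¹ μm⁻¹) and optionally remote-sensing reflectance
    ``r_rs`` (sr⁻¹); geolocated and timestamped, with coincident PAR
    (μmol photons m⁻² s⁻¹).
    """

    wavelengths: np.ndarray
    l_w: np.ndarray
    timestamp: pd.Timestamp
    lat: float
    lon: float
    par: float
    r_rs: np.ndarray | None = None

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.l_w = np.asarray(self.l_w, dtype=float)
        if self.wavelengths.ndim != 1 or np.any(np.diff(self.wavelengths) <= 0):
            raise InvalidInputError("wavelength grid must be strictly increasing")
        if self.l_w.shape != self.wavelengths.shape:
            raise InvalidInputError("l_w and wavelengths shapes differ")
        if self.r_rs is not None:
            self.r_rs = np.asarray(self.r_rs, dtype=float)
            if self.r_rs.shape != self.wavelengths.shape:
                raise InvalidInputError("r_rs and wavelengths shapes differ")
        self.timestamp = pd.Timestamp(self.timestamp)


@dataclass
class OC3Coefficients:
    """Maximum-band-ratio polynomial for chlorophyll a retrieval.

    chl = 10^(c0 + c1·r + c2·r² + c3·r³ + c4·r⁴) with
    r = log10(max(Rrs(blue1), Rrs(blue2)) / Rrs(green)).

    The coefficient vintage is configuration; the default is the
    operational MODIS OC3 set (bands 443/488 over 547).
    """

    coeffs: tuple[float, float, float, float, float]
    blue1: float = 443.0
    blue2: float = 488.0
    green: float = 547.0


OC3_MODIS_DEFAULT = OC3Coefficients(
    coeffs=(0.2424, -2.7423, 1.8017, 0.0015, -1.2280)
)


def band_value(
    wavelengths: np.ndarray,
    values: np.ndarray,
    center: float,
    halfwidth: float = 2.0,
) -> float:
    """Band radiance/reflectance at a nominal centre wavelength.

    Mean of samples within ±``halfwidth`` nm; linear interpolation
    between adjacent grid points when the window is empty.  NaN when the
    centre lies outside the grid.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.asarray(values, dtype=float)
    if center < wavelengths[0] or center > wavelengths[-1]:
        return np.nan
    sel = np.abs(wavelengths - center) <= halfwidth
    if np.any(sel):
        return float(np.mean(values[sel]))
    return float(np.interp(center, wavelengths, values))


def compute_flh(
    s: Spectrum, bands: tuple[float, float, float] = FLH_BANDS
) -> float:
    """Fluorescence line height above the 667–748 nm linear baseline.

    Returns NaN when any of the three bands is outside the spectrum's
    coverage.  Affine-in-wavelength spectral components contribute
    nothing (the baseline subtraction annihilates them).
    """
    b0, b1, b2 = bands
    l0 = band_value(s.wavelengths, s.l_w, b0)
    l1 = band_value(s.wavelengths, s.l_w, b1)
    l2 = band_value(s.wavelengths, s.l_w, b2)
    if not (np.isfinite(l0) and np.isfinite(l1) and np.isfinite(l2)):
        return np.nan
    return l1 - l0 - (l2 - l0) * (b1 - b0) / (b2 - b0)


def compute_oc3_chl(
    s: Spectrum, oc3: OC3Coefficients = OC3_MODIS_DEFAULT
) -> float:
    """OC3 maximum-band-ratio chlorophyll a (mg m⁻³) from R_RS.

    NaN when reflectances are missing or non-positive.
    """
    if s.r_rs is None:
        return np.nan
    rb1 = band_value(s.wavelengths, s.r_rs, oc3.blue1)
    rb2 = band_value(s.wavelengths, s.r_rs, oc3.blue2)
    rg = band_value(s.wavelengths, s.r_rs, oc3.green)
    if not (np.isfinite(rb1) and np.isfinite(rb2) and np.isfinite(rg)):
        return np.nan
    blue = max(rb1, rb2)
    if blue <= 0 or rg <= 0:
        return np.nan
    r = np.log10(blue / rg)
    c = oc3.coeffs
    return float(10.0 ** (c[0] + c[1] * r + c[2] * r**2 + c[3] * r**3 + c[4] * r**4))


def oc3_inverse_ratio(
    chl: float, oc3: OC3Coefficients = OC3_MODIS_DEFAULT
) -> float:
    """Log band ratio r that the OC3 polynomial maps to ``chl``.

    Numerical inversion over the algorithm's monotone validity range;
    used by the synthetic generator to construct reflectance spectra
    consistent with a prescribed chlorophyll concentration.
    """
    from scipy.optimize import brentq

    c = oc3.coeffs
    f = lambda r: (c[0] + c[1] * r + c[2] * r**2 + c[3] * r**3 + c[4] * r**4
                   - np.log10(chl))
    return float(brentq(f, -0.4, 1.2))


def local_solar_time(timestamp: pd.Timestamp, lon: float) -> float:
    """Local solar time in hours: UTC + longitude / 15°."""
    ts = pd.Timestamp(timestamp)
    utc_hours = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    return (utc_hours + lon / 15.0) % 24.0


def build_yield_series(
    spectra,
    extracted_chl: pd.DataFrame | None = None,
    oc3: OC3Coefficients = OC3_MODIS_DEFAULT,
    flh_bands: tuple[float, float, float] = FLH_BANDS,
    rolling_minutes: float | None = None,
) -> pd.DataFrame:
    """Per-record FLH, OC3 chlorophyll and passive yield F/Chl.

    Records where chlorophyll is missing or non-positive get NaN yield.
    ``rolling_minutes`` (e.g. 25) adds a ``fchl_smooth`` column, the
    centred time-based rolling mean of the yield.  When a table of
    solvent-extracted chlorophyll (columns ``timestamp``, ``chl``) is
    supplied, a type II cross-validation regression of OC3 against
    extracted values is attached as ``df.attrs['oc3_validation']``.
    """
    rows = []
    for s in spectra:
        flh = compute_flh(s, bands=flh_bands)
        chl = compute_oc3_chl(s, oc3=oc3)
        fchl = flh / chl if np.isfinite(chl) and chl > 0 else np.nan
        rows.append(
            {
                "timestamp": s.timestamp,
                "lat": s.lat,
                "lon": s.lon,
                "par": s.par,
                "flh": flh,
                "chl": chl,
                "fchl": fchl,
                "local_time": local_solar_time(s.timestamp, s.lon),
            }
        )
    df = pd.DataFrame(rows)
    if rolling_minutes is not None:
        df["fchl_smooth"] = rolling_mean(
            df["timestamp"], df["fchl"].values, window=rolling_minutes
        )
    if extracted_chl is not None and len(extracted_chl) >= 3:
        merged = pd.merge_asof(
            df.sort_values("timestamp"),
            extracted_chl.sort_values("timestamp").rename(
                columns={"chl": "chl_extracted"}
            ),
            on="timestamp",
            tolerance=pd.Timedelta(minutes=30),
            direction="nearest",
        ).dropna(subset=["chl", "chl_extracted"])
        if len(merged) >= 3:
            df.attrs["oc3_validation"] = rma_regression(
                merged["chl_extracted"].values, merged["chl"].values
            )
    return df


def midday_extract(
    series: pd.DataFrame, window: tuple[float, float] = (12.0, 15.0)
) -> pd.DataFrame:
    """Records within the local-solar-time window (bounds inclusive).

    The default 12:00–15:00 window approximately matches the MODIS-Aqua
    overpass timing.  Returns the empty frame (with a warning) when no
    record falls inside the window.
    """
    lo, hi = window
    out = series[(series["local_time"] >= lo) & (series["local_time"] <= hi)]
    if out.empty:
        import warnings

        warnings.warn("no records inside the midday window", stacklevel=2)
    return out.copy()


def daily_midday_stats(midday: pd.DataFrame) -> pd.DataFrame:
    """Daily mean and SD of the midday passive yield."""
    g = midday.groupby(midday["timestamp"].dt.date)["fchl"]
    return pd.DataFrame({"mean": g.mean(), "sd": g.std(), "n": g.count()})


def par_response(
    series: pd.DataFrame, bins=None
) -> tuple[pd.DataFrame, TanhFitResults]:
    """PAR-binned mean yield and the fitted saturating light response.

    Empty bins are omitted from the fit.  Returns the bin table
    (``par_mid``, ``fchl_mean``, ``fchl_sd``, ``n``) and the
    :class:`~ferrolux.stats_core.TanhFitResults`; a flat response is
    returned with ``degenerate=True`` rather than an error.
    """
    if bins is None:
        bins = np.arange(0.0, 2200.0, 100.0)
    bins = np.asarray(bins, dtype=float)
    data = series.dropna(subset=["par", "fchl"])
    idx = np.digitize(data["par"].values, bins)
    rows = []
    for i in range(1, len(bins)):
        sel = data[idx == i]
        if sel.empty:
            continue
        rows.append(
            {
                "par_mid": 0.5 * (bins[i - 1] + bins[i]),
                "fchl_mean": sel["fchl"].mean(),
                "fchl_sd": sel["fchl"].std(),
                "n": len(sel),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 5:
        raise InvalidInputError(
            "need at least 5 non-empty PAR bins for the light-response fit"
        )
    fit = fit_tanh_response(table["par_mid"].values, table["fchl_mean"].values)
    return table, fit
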