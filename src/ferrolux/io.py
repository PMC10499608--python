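"""File formats, run configuration and the pipeline orchestrator.

Conventions used throughout: latitudes north-positive, longitudes in
[−180, 180), time axes at composite mid-points, all stated interval
bounds closed.  Gridded fields travel as CF-style NetCDF (classic
format via the scipy backend); tables as CSV; reports as JSON; run
configuration as YAML.  Every pipeline run writes a resolved-config
snapshot next to its outputs so results are reproducible bit-for-bit
given the same config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import field_physiology as fp
from . import satellite_processing as sat
from . import ship_radiometry as ship
from .fe_limitation import ScalingSpec, SensitivityModel, model_fe_lim
from .stats_core import InvalidInputError, anova_tukey
from .synthetic_data import (
    SceneConfig,
    ShipSimConfig,
    gen_bioassay,
    gen_diel_frrf,
    gen_model_limitation,
    gen_satellite_record,
    gen_ship_transect,
)

__all__ = [
    "read_gridded",
    "write_gridded",
    "read_ship_csv",
    "write_ship_csv",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("ferrolux")


class FormatError(ValueError):
    """Raised for structurally invalid input files."""


def _check_axes(obj):
    for axis in ("time", "lat", "lon"):
        if axis in obj.dims:
            vals = obj[axis].values
            diffs = np.diff(vals.astype("int64") if axis == "time" else vals)
            if vals.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise FormatError(f"axis {axis!r} is not strictly monotone")


def read_gridded(path, variable: str) -> xr.DataArray:
    """Read one variable of a CF-style NetCDF grid, validated.

    Axes must be strictly monotone; the units attribute is preserved;
    missing values arrive as NaN (xarray decoding).
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise FormatError(
                f"variable {variable!r} not in {path} "
                f"(has: {', '.join(ds.data_vars)})"
            )
        da = ds[variable].load()
    _check_axes(da)
    return da


def write_gridded(obj, path) -> None:
    """Write a DataArray or Dataset as classic-format NetCDF."""
    if isinstance(obj, xr.DataArray):
        obj = obj.to_dataset(name=obj.name or "field")
    # scipy backend writes NetCDF-3: drop unsupported attribute types
    obj = obj.copy()
    obj.attrs = {
        k: v for k, v in obj.attrs.items()
        if isinstance(v, (str, int, float, np.integer, np.floating))
    }
    obj.to_netcdf(path, engine="scipy")


def write_ship_csv(spectra, path) -> None:
    """Wide per-timestamp hyperspectral CSV: one column per wavelength."""
    rows = []
    for s in spectra:
        row = {
            "timestamp": s.timestamp.isoformat(),
            "lat": s.lat,
            "lon": s.lon,
            "par": s.par,
        }
        row.update({f"lw_{w:.1f}": v for w, v in zip(s.wavelengths, s.l_w)})
        if s.r_rs is not None:
            row.update(
                {f"rrs_{w:.1f}": v for w, v in zip(s.wavelengths, s.r_rs)}
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ship_csv(path) -> list:
    """Read the wide hyperspectral CSV back into Spectrum records."""
    df = pd.read_csv(path)
    lw_cols = sorted(
        (c for c in df.columns if c.startswith("lw_")),
        key=lambda c: float(c[3:]),
    )
    rrs_cols = sorted(
        (c for c in df.columns if c.startswith("rrs_")),
        key=lambda c: float(c[4:]),
    )
    if not lw_cols:
        raise FormatError(f"no lw_<wavelength> columns in {path}")
    wl = np.array([float(c[3:]) for c in lw_cols])
    out = []
    for _, row in df.iterrows():
        out.append(
            ship.Spectrum(
                wavelengths=wl,
                l_w=row[lw_cols].to_numpy(dtype=float),
                r_rs=row[rrs_cols].to_numpy(dtype=float) if rrs_cols else None,
                timestamp=pd.Timestamp(row["timestamp"]),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                par=float(row["par"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Run configuration and orchestration
# ---------------------------------------------------------------------------

ALL_STAGES = ("simulate", "ship", "field", "satellite", "compare")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    seed: int = 0
    months: int = 220
    s_true: float = 0.03
    s_model: float = 0.06
    ship_days: int = 4
    stages: tuple = ALL_STAGES
    box: tuple = sat.NINO3_BOX
    chl_range: tuple = (0.1, 0.4)
    overpass_local_time: float = 13.5
    fchl_upper: float = 0.7
    lim_max: float = 0.78
    scan_pct: float = 10.0
    n_boot: int = 1999
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("stages", "box", "chl_range"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(self).items()
                },
                fh,
                sort_keys=False,
            )


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute the selected stages; return the machine-readable report.

    Stage chain: simulate (scene, model fields, ship transect, FRRf,
    bioassay) → ship (FLH, OC3, midday yields, PAR response) → field
    (Fv/Fm, night yields, growth rates, ±Fe pool) → satellite
    (denormalize, mask, F/Chl, regional series) → compare (scaled obs
    vs model limitation sensitivity to ΔSST).  Deterministic for a given
    config; outputs plus a resolved-config snapshot land in ``outdir``.
    """
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "resolved_config.yaml")
    report: dict = {"seed": cfg.seed}

    scene_cfg = SceneConfig(
        seed=cfg.seed,
        months=cfg.months,
        s_true=cfg.s_true,
        fchl_upper=cfg.fchl_upper,
        lim_max=cfg.lim_max,
        overpass_local_time=cfg.overpass_local_time,
    )
    ship_cfg = ShipSimConfig(seed=cfg.seed, n_days=cfg.ship_days)

    scene = model = spectra = frrf_fe = frrf_n = bioassay = None

    if "simulate" in cfg.stages:
        scene = gen_satellite_record(scene_cfg)
        model = gen_model_limitation(scene_cfg, s_model=cfg.s_model)
        spectra = gen_ship_transect(ship_cfg)
        frrf_fe = gen_diel_frrf(regime="fe", seed=cfg.seed)
        frrf_n = gen_diel_frrf(regime="n", seed=cfg.seed)
        bioassay = gen_bioassay(seed=cfg.seed)
        write_gridded(scene, outdir / "scene.nc")
        write_gridded(model, outdir / "model.nc")
        write_ship_csv(spectra, outdir / "ship.csv")
        bioassay.to_csv(outdir / "bioassay.csv", index=False)
        frrf_fe.to_csv(outdir / "frrf_fe.csv", index=False)
        frrf_n.to_csv(outdir / "frrf_n.csv", index=False)
        log.info(
            "simulate: %d months x %d x %d grid, %d spectra",
            cfg.months, scene.sizes["lat"], scene.sizes["lon"], len(spectra),
        )

    if "ship" in cfg.stages:
        if spectra is None:
            spectra = read_ship_csv(outdir / "ship.csv")
        yields = ship.build_yield_series(spectra)
        midday = ship.midday_extract(yields)
        fe_zone = midday[midday["lon"] < ship_cfg.changepoint_lon]
        n_zone = midday[midday["lon"] >= ship_cfg.changepoint_lon]
        ratio = fe_zone["fchl"].mean() / n_zone["fchl"].mean()
        bins, fit = ship.par_response(
            yields[yields["lon"] < ship_cfg.changepoint_lon]
        )
        yields.to_csv(outdir / "ship_yields.csv", index=False)
        report["ship"] = {
            "n_records": int(len(yields)),
            "n_midday": int(len(midday)),
            "midday_fchl_regime_ratio": float(ratio),
            "tanh_a": fit.a,
            "tanh_b": fit.b,
            "par_at_95pct_plateau": fit.par_at_fraction(0.95),
        }
        log.info("ship: midday regime ratio %.2f", ratio)

    if "field" in cfg.stages:
        if frrf_fe is None:
            frrf_fe = pd.read_csv(
                outdir / "frrf_fe.csv", parse_dates=["timestamp"]
            )
            frrf_n = pd.read_csv(
                outdir / "frrf_n.csv", parse_dates=["timestamp"]
            )
            bioassay = pd.read_csv(outdir / "bioassay.csv")
        night_yields = {}
        for name, df, chl in (
            ("fe", frrf_fe, frrf_fe.attrs.get("extracted_chl", 0.25)),
            ("n", frrf_n, frrf_n.attrs.get("extracted_chl", 0.25)),
        ):
            part = fp.diel_partition(df)
            blank = df["blank"].to_numpy()
            fv = fp.fvfm(df["f_o"].to_numpy(), df["f_m"].to_numpy(), blank)
            night_fluor = (df["f_o"] - df["blank"])[part["is_night"]]
            night_yields[name] = fp.fchl_active(night_fluor.to_numpy(), chl)
            report.setdefault("field", {})[f"fvfm_mean_{name}"] = float(
                np.mean(fv)
            )
        report["field"]["active_fchl_regime_ratio"] = (
            night_yields["fe"] / night_yields["n"]
        )
        control = bioassay.loc[
            bioassay["treatment"] == "control", "chl"
        ].mean()
        rates = bioassay[bioassay["treatment"] != "control"].assign(
            mu=lambda d: fp.net_growth_rate(d["chl"].to_numpy(), control)
        )
        groups = {
            t: g["chl"].to_numpy() for t, g in bioassay.groupby("treatment")
        }
        aov = anova_tukey(groups)
        rates.to_csv(outdir / "growth_rates.csv", index=False)
        report["field"].update(
            {
                "anova_f": aov.f_statistic,
                "anova_p": aov.p_value,
                "mu_fe": float(
                    rates.loc[rates["treatment"] == "+Fe", "mu"].mean()
                ),
            }
        )
        log.info(
            "field: active F/Chl ratio %.2f",
            report["field"]["active_fchl_regime_ratio"],
        )

    obs_series = model_series = None
    if "satellite" in cfg.stages:
        if scene is None:
            nflh = read_gridded(outdir / "scene.nc", "nflh")
            chl = read_gridded(outdir / "scene.nc", "chl")
            sst = read_gridded(outdir / "scene.nc", "sst")
        else:
            nflh, chl, sst = scene["nflh"], scene["chl"], scene["sst"]
        flh = sat.denormalize_nflh(nflh, cfg.overpass_local_time)
        mask = sat.mask_chl(chl, *cfg.chl_range)
        n_kept = int(mask.sum())
        fchl = sat.fchl_sat(flh, chl, mask)
        obs_series = sat.region_series(fchl, box=cfg.box)
        sst_series = sat.region_series(sst.where(mask), box=cfg.box)
        obs_series["sst"] = sst_series["value"]
        obs_series.to_csv(outdir / "obs_series.csv")
        report["satellite"] = {
            "pixels_kept": n_kept,
            "pixels_total": int(mask.size),
            "months": int(len(obs_series)),
        }
        log.info(
            "satellite: mask retained %d/%d pixels", n_kept, mask.size
        )

    if "compare" in cfg.stages:
        if model is None:
            model = xr.open_dataset(outdir / "model.nc", engine="scipy").load()
        fe_lim = model_fe_lim(
            [model["l_fe_diatom"], model["l_fe_nano"]],
            [model["biomass_diatom"], model["biomass_nano"]],
        )
        model_series = sat.region_series(fe_lim, box=cfg.box)
        if obs_series is None:
            obs_series = pd.read_csv(
                outdir / "obs_series.csv", index_col=0, parse_dates=True
            )
        scaling = ScalingSpec(fchl_upper=cfg.fchl_upper, lim_max=cfg.lim_max)
        sens = SensitivityModel(
            obs_series["value"].values,
            model_series["value"].values,
            obs_series["sst"].values,
            scaling=scaling,
        ).fit(scan_pct=cfg.scan_pct, seed=cfg.seed, n_boot=cfg.n_boot)
        report["compare"] = sens.to_dict()
        report["compare"]["threshold_scan"] = (
            sens.threshold_scan.to_dict("records")
            if sens.threshold_scan is not None
            else None
        )
        (outdir / "sensitivity_summary.txt").write_text(sens.summary() + "\n")
        log.info("compare: model/obs ratio %.2f", sens.ratio)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
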