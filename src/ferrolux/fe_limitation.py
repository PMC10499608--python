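"""Iron-limitation index and the observation–model sensitivity comparison.

The satellite passive fluorescence yield F/Chl_sat is mapped onto the
range of a biogeochemical model's iron-limitation term by an affine
scaling: the lower anchor (default F/Chl = 0) maps to limitation 0 and
the upper anchor (default 0.7 W m⁻² sr⁻¹ μm⁻¹ [mg Chl m⁻³]⁻¹, the global
pixel-fraction asymptote) maps to the model's maximum limitation
(default 0.78).  On the model side, the per-group fractional limitation
of maximal growth L_Fe (0–1, higher = less limited) is biomass-weighted
across phytoplankton groups and subtracted from one,

    Fe_Lim = 1 − Σᵢ biomassᵢ · L_Fe,ᵢ / Σᵢ biomassᵢ,

so that higher values mean stronger iron limitation.

The emergent-constraint statistic is the ratio of the model's to the
observations' ranged-major-axis slope of limitation anomalies on SST
anomalies in the Niño3 region — a value of ~2 means the model's iron
limitation is twice as sensitive to ENSO-driven SST changes as the
satellite diagnostic implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import InvalidInputError, RMAResults, RangedMajorAxis

__all__ = [
    "ScalingSpec",
    "scale_fchl",
    "model_fe_lim",
    "SensitivityModel",
    "SensitivityResults",
]


@dataclass
class ScalingSpec:
    """Affine map from F/Chl_sat to the model limitation range.

    ``fchl_lower`` maps to limitation 0 and ``fchl_upper`` to
    ``lim_max``; values outside are clipped to [0, lim_max] when
    ``clip`` is set.  ``lim_max`` is sourced from the model's own
    maximum limitation, never inferred from the data.
    """

    fchl_lower: float = 0.0
    fchl_upper: float = 0.7
    lim_max: float = 0.78
    clip: bool = True

    def __post_init__(self):
        if not self.fchl_upper > self.fchl_lower:
            raise InvalidInputError("fchl_upper must exceed fchl_lower")
        if not 0 < self.lim_max <= 1:
            raise InvalidInputError("lim_max must be in (0, 1]")

    @property
    def gain(self) -> float:
        """Limitation units per F/Chl unit below the clip."""
        return self.lim_max / (self.fchl_upper - self.fchl_lower)

    def rescaled_upper(self, pct: float) -> "ScalingSpec":
        """Copy with the upper anchor perturbed by ``pct`` percent."""
        return ScalingSpec(
            fchl_lower=self.fchl_lower,
            fchl_upper=self.fchl_upper * (1.0 + pct / 100.0),
            lim_max=self.lim_max,
            clip=self.clip,
        )


def scale_fchl(fchl, spec: ScalingSpec = ScalingSpec()):
    """Map F/Chl (scalar, array or DataArray) to the limitation scale."""
    lim = spec.gain * (fchl - spec.fchl_lower)
    if spec.clip:
        lim = lim.clip(0.0, spec.lim_max) if hasattr(lim, "clip") else float(
            np.clip(lim, 0.0, spec.lim_max)
        )
    return lim


def model_fe_lim(l_fe_groups, biomass_groups):
    """Biomass-weighted model iron-limitation term Fe_Lim = 1 − ⟨L_Fe⟩.

    ``l_fe_groups`` and ``biomass_groups`` are sequences of per-group
    fields (arrays or DataArrays, any matching shape).  L_Fe values must
    lie in [0, 1]; biomasses must be non-negative with a positive total.
    Invariant to a uniform rescaling of all biomasses.
    """
    if len(l_fe_groups) != len(biomass_groups) or len(l_fe_groups) == 0:
        raise InvalidInputError("need matching, non-empty group lists")
    num = None
    den = None
    for l_fe, bio in zip(l_fe_groups, biomass_groups):
        l_arr = np.asarray(getattr(l_fe, "values", l_fe), dtype=float)
        b_arr = np.asarray(getattr(bio, "values", bio), dtype=float)
        if np.nanmin(l_arr) < 0 or np.nanmax(l_arr) > 1:
            raise InvalidInputError("L_Fe values must lie in [0, 1]")
        if np.nanmin(b_arr) < 0:
            raise InvalidInputError("biomasses must be non-negative")
        term = l_fe * bio
        num = term if num is None else num + term
        den = bio if den is None else den + bio
    den_arr = np.asarray(getattr(den, "values", den), dtype=float)
    if np.any(den_arr == 0):
        raise InvalidInputError("zero total biomass in at least one cell")
    fe_lim = 1.0 - num / den
    if hasattr(fe_lim, "name"):
        fe_lim.name = "fe_lim"
        fe_lim.attrs["units"] = "1"
    return fe_lim


@dataclass
class SensitivityResults:
    """Observation vs model iron-limitation SST sensitivities.

    ``ratio`` is model slope / observation slope; ``reliable`` is False
    when the observational slope's bootstrap CI spans zero, in which
    case the ratio is not interpretable.  ``threshold_scan`` repeats the
    observational regression with the scaling upper anchor perturbed.
    """

    obs: RMAResults
    model: RMAResults
    ratio: float
    reliable: bool
    scaling: ScalingSpec
    threshold_scan: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Iron-limitation sensitivity to SST anomalies (Nino3)",
            "  observations (scaled F/Chl_sat):",
            "    " + self.obs.summary().replace("\n", "\n    "),
            "  model (biomass-weighted Fe_Lim):",
            "    " + self.model.summary().replace("\n", "\n    "),
            f"  model / observation slope ratio: {self.ratio:.3f}"
            + ("" if self.reliable else "  [UNRELIABLE: obs CI spans 0]"),
        ]
        if self.threshold_scan is not None:
            lines.append("  upper-anchor scan:")
            lines.append(
                "    " + self.threshold_scan.to_string(index=False).replace(
                    "\n", "\n    "
                )
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "obs_slope": self.obs.slope,
            "obs_r_squared": self.obs.r_squared,
            "obs_p_value": self.obs.p_value,
            "model_slope": self.model.slope,
            "model_r_squared": self.model.r_squared,
            "model_p_value": self.model.p_value,
            "ratio": self.ratio,
            "reliable": self.reliable,
            "n": self.obs.n,
        }

    def plot(self, ax=None):
        """Scatter of both anomaly regressions with their RMA lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.axhline(0, lw=0.5, color="0.7")
        ax.axvline(0, lw=0.5, color="0.7")
        ax.set_xlabel("ΔSST (°C)")
        ax.set_ylabel("Δ iron limitation")
        ax.set_title(
            f"model/obs sensitivity ratio = {self.ratio:.2f}"
        )
        return ax


class SensitivityModel:
    """Paired regression model for the emergent-constraint comparison.

    Parameters
    ----------
    obs_fchl : series of regional monthly F/Chl_sat (raw, unscaled)
    model_fe_lim : series of regional monthly model Fe_Lim
    sst : series of regional monthly SST (°C), aligned with both
    scaling : the F/Chl → limitation affine map

    ``fit`` converts all three series to anomalies (value minus record
    average), scales the observational series, and regresses each
    limitation series on ΔSST by ranged major axis.
    """

    def __init__(
        self,
        obs_fchl,
        model_fe_lim,
        sst,
        scaling: ScalingSpec = ScalingSpec(),
    ):
        obs = pd.Series(obs_fchl).astype(float)
        mod = pd.Series(model_fe_lim).astype(float)
        sst = pd.Series(sst).astype(float)
        n = min(len(obs), len(mod), len(sst))
        if not (len(obs) == len(mod) == len(sst)):
            raise InvalidInputError("series lengths differ")
        if n < 24:
            raise InvalidInputError(
                "need at least 24 months for anomaly regressions"
            )
        self.obs_fchl = obs
        self.model_series = mod
        self.sst = sst
        self.scaling = scaling

    def fit(
        self,
        scan_pct: float = 10.0,
        seed: int = 0,
        n_boot: int = 1999,
    ) -> SensitivityResults:
        dsst = (self.sst - self.sst.mean()).values

        def obs_fit(spec: ScalingSpec, seed_offset: int = 0) -> RMAResults:
            lim = scale_fchl(self.obs_fchl, spec)
            dlim = (lim - lim.mean()).values
            return RangedMajorAxis(dlim, dsst).fit(
                n_boot=n_boot, seed=seed + seed_offset
            )

        obs_res = obs_fit(self.scaling)
        dmod = (self.model_series - self.model_series.mean()).values
        model_res = RangedMajorAxis(dmod, dsst).fit(n_boot=n_boot, seed=seed + 1)

        reliable = not (obs_res.slope_ci_low <= 0.0 <= obs_res.slope_ci_high)
        ratio = model_res.slope / obs_res.slope if obs_res.slope != 0 else np.nan

        scan_rows = []
        if scan_pct:
            for pct in (-scan_pct, 0.0, scan_pct):
                spec = self.scaling.rescaled_upper(pct)
                r = obs_fit(spec, seed_offset=2)
                scan_rows.append(
                    {
                        "upper_anchor_pct": pct,
                        "fchl_upper": spec.fchl_upper,
                        "obs_slope": r.slope,
                        "ratio": model_res.slope / r.slope,
                    }
                )
        scan = pd.DataFrame(scan_rows) if scan_rows else None

        return SensitivityResults(
            obs=obs_res,
            model=model_res,
            ratio=float(ratio),
            reliable=reliable,
            scaling=self.scaling,
            threshold_scan=scan,
        )
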