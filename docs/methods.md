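# Methods

This note documents the models, estimators, synthetic-data assumptions
and numerical choices behind `ferrolux`, in the order the pipeline runs.

## Fluorescence line height and the passive yield

Sun-induced chlorophyll fluorescence produces a radiance peak near
683 nm. FLH measures its height above a linear baseline between the
667 nm and 748 nm bands:

    FLH = L678 − L667 − (L748 − L667) · (678 − 667) / (748 − 667)

evaluated at the MODIS-Aqua waveband centres. Because the baseline
construction is affine in wavelength, any spectral component that is
itself affine over 667–748 nm contributes exactly zero — the key
robustness property, verified to 1e−12 in the tests. Band radiances
are the mean of spectral samples within ±2 nm of each centre, falling
back to linear interpolation between adjacent grid points; the ±2 nm
half-width matches typical hyperspectral radiometer resolution and is
configurable.

The passive yield F/Chl = FLH / Chl normalizes out biomass. Shipboard
chlorophyll comes from the OC3 maximum-band-ratio polynomial
`chl = 10^(Σ cᵢ rⁱ)`, `r = log10(max(Rrs443, Rrs488)/Rrs547)`; the
coefficient vintage is configuration (default: the operational MODIS
set) because retrievals differ across reprocessings.

Midday extraction keeps records with local solar time in
[12:00, 15:00], bounds closed, with local solar time = UTC +
longitude/15°. This window approximates the satellite overpass, when
incident PAR is high enough that the fluorescence yield sits on its
light-saturated plateau.

## The light response

F/Chl rises with PAR and saturates. We fit

    F/Chl(PAR) = a · tanh(b · PAR / a)

by bounded least squares (`scipy.optimize.curve_fit`, positivity
bounds, data-driven initial values): `a` is the plateau (yield units),
`b` the initial slope (yield per μmol photons m⁻² s⁻¹); the curve's
derivative at zero is exactly `b` and its limit is `a`. A constant
response carries no saturation information and is returned flagged
`degenerate` rather than fitted. Saturation PAR is reported as the PAR
at 95% of the plateau, `(a/b)·atanh(0.95)`; under the default
synthetic conditions this lies near 550 μmol photons m⁻² s⁻¹, i.e.
overpass irradiances (>500) are saturating.

## Satellite processing

The level-3 nFLH product removes solar/viewing geometry by
normalization. Since the yield is light-saturated at overpass, we undo
the normalization: FLH = nFLH × cos(SZA), with the solar zenith angle
computed per pixel latitude at the composite's mid-time point and the
13:30 local overpass hour (both configurable). SZA uses the Spencer
Fourier-series declination plus the hour angle; it is validated to
<0.5° against a NOAA solar-position transcription in the tests, and
flagged outside |lat| ≤ 66°. Pixels with the sun at or below the
horizon are masked.

Chlorophyll masking keeps 0.1 ≤ chl ≤ 0.4 mg m⁻³ — below, FLH is near
its detection limit; above, the chlorophyll–absorption relation turns
nonlinear. The exclusion thresholds are strict inequalities, so
boundary values are retained.

Regional series are cos(latitude)-weighted area means per month over
the Niño3 box (5°S–5°N, 150°W–90°W by default; the weighting is
negligible this close to the equator but documented). Months with less
than 20% valid pixels are flagged invalid. Anomalies subtract the
full-record mean by default; a per-calendar-month climatology mode is
provided for removing the seasonal cycle, without asserting which the
reference analyses used. The F/Chl ratio is computed per pixel and
then averaged (ratio-then-average), the default order where the
alternative is not stated. Track averaging selects unmasked pixels
within a 100 km great-circle radius of each ship position.

## Type II regression (ranged major axis)

Both ΔSST and Δlimitation carry observational error, so ordinary least
squares would attenuate slopes. The ranged-major-axis estimator:

1. range-transform each variable to [0, 1]: `u = (x − min x)/range(x)`;
2. take the major-axis (leading principal axis) slope of the
   transformed cloud, via the closed-form root of the 2×2 covariance
   eigenproblem;
3. back-transform by `range(y)/range(x)` and set the intercept through
   the bivariate means.

R² is the squared Pearson correlation. The association p-value is the
two-tailed Pearson t-test — significance of association does not
depend on the slope convention — with a permutation alternative
(`n_permutations > 0`). Slope CIs are percentile bootstrap over pairs
(1,999 resamples by default, seeded, vectorised); no closed-form CI is
assumed for the ranged estimator. Zero range in either variable makes
the ranging transform undefined and is an error, never a silent
fallback. Note the type II estimand: it is consistent for the
underlying linear relation when error SDs are proportional to the
variable ranges; with error confined to one variable it estimates the
functional (not the regression) slope, which is the intended behaviour.

## Iron-limitation scaling and the sensitivity ratio

F/Chl_sat maps onto a model-comparable limitation index by the affine
scaling `lim = lim_max · (F/Chl − lower)/(upper − lower)`, clipped to
[0, lim_max]. Defaults: lower anchor 0 (no iron limitation at zero
yield), upper anchor 0.7 W m⁻² sr⁻¹ μm⁻¹ [mg Chl m⁻³]⁻¹ (the global
pixel-fraction asymptote of the yield distribution), ceiling
lim_max = 0.78 (the maximum limitation the reference model attains —
configuration sourced from the model, never fit to data). The model
term is Fe_Lim = 1 − Σ bᵢ L_Fe,ᵢ / Σ bᵢ over phytoplankton groups,
with L_Fe the fractional limitation of maximal growth and bᵢ carbon
biomass; it is invariant to uniform biomass rescaling.

`SensitivityModel.fit()` regresses scaled observational limitation
anomalies and model Fe_Lim anomalies on ΔSST (both by ranged major
axis, for symmetry) and reports the slope ratio model/obs. The ratio
is flagged unreliable when the observational slope's bootstrap CI
spans zero. A ±10% perturbation of the upper anchor rescales the
affine gain, so on clip-free data the ratio moves by exactly the
perturbation factor — never more; clipping or nonlinearity can only
shrink this. The scan table in the results makes that bound auditable.

## Active fluorometry and bioassays

Fv/Fm = ((Fm − b) − (Fo − b))/(Fm − b) after subtracting the filtrate
blank b from both channels. b ≥ Fm invalidates a record; b > Fo is
computed but flagged suspicious. Since Fv is blank-invariant while the
denominator shrinks, any positive blank strictly raises Fv/Fm.

Night is solar elevation < 0 (astronomical), computed from each
record's position and local solar time; a PAR-threshold mode exists
because "night" is not otherwise defined numerically. Night-time
F/Chl_active is the mean night fluorescence divided by
solvent-extracted chlorophyll. Bioassay net growth rates use
μ = ln(Chl_treatment/Chl_control)/t with the control (not initial)
bottle as reference, absorbing shared photoacclimation drift, and
t = 2 days by default. The pooled ±Fe contrast assigns any treatment
whose label contains "Fe" to the +Fe pool and compares pools by a
Welch t-test (pooled-variance optional); degenerate equal-constant
samples return p = 1 by convention.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (config, seed) and define the
package's study conditions:

* **Satellite scene** (default 220 months, 1° grid over the Niño3
  box): SST = 26 °C + an AR(1) ENSO anomaly (stationary SD 1 °C,
  monthly persistence 0.9) times a smooth O(1) spatial mode; true
  limitation L = clip(0.40 + 0.03·ΔSST, 0, 0.78); true yield is the
  affine inverse of the analysis scaling (anchor 0.7 ↔ 0.78);
  chlorophyll = 0.25 − 0.02·ΔSST mg m⁻³ (warm = less biomass);
  nFLH = yield × chl / cos(SZA); 5% relative noise on nFLH and
  chlorophyll, 0.05 °C on SST. The chlorophyll range keeps ≥95% of
  pixels inside the satellite mask.
* **Model fields**: two groups (diatom, nanophytoplankton) with
  L_Fe = L0 − 0.06·ΔSST sharing the scene's ENSO series, constant
  spatially varying biomass weights, 0.02 additive noise — so the
  biomass-weighted Fe_Lim has twice the observational sensitivity by
  construction.
* **Ship transect** (6 days, 5-min cadence): Gaussian emission peak at
  683 nm (σ = 10 nm) on a broad smooth baseline; peak amplitude =
  regime plateau × tanh(PAR/300) × chl, divided by the unit-peak FLH
  factor so the measurement operator inverts it exactly; regime
  plateau ratio 3.5 across the change-point longitude; reflectance
  spectra constructed to invert OC3 at the prescribed chlorophyll.
* **Bioassays**: triplicate lognormal (median-1 noise, CV 10%)
  responses; iron addition doubles chlorophyll at an iron-limited site.
* **Diel fluorometry**: regime-dependent base Fv/Fm (0.32 vs 0.47)
  with midday quenching dips and an iron-regime night-time dip, σPSII
  contrast, 3.2-fold chlorophyll-normalized Fo contrast, and the blank
  added to both channels.

What the generators deliberately do **not** emulate: radiative
transfer and atmospheric correction, clouds and realistic missing-data
masks, Raman/CDOM spectral structure, community composition shifts,
non-AR(1) ENSO dynamics, and any feedback of biology on SST.
Consequently, passing recovery tests demonstrates that the estimators
and the plumbing are correct and unbiased under the assumed error
structure — not that the diagnostic is immune to the structured
artefacts of real ocean-colour data. The near-unity R² of the synthetic
regional regressions (hundreds of pixels average the pixel noise away)
is likewise a property of the idealized noise model, not a claim about
real records.

## Numerical choices and problem sizes

Recovery checks run at 220 months on the 1° Niño3 grid with 20 seeds,
the transect demos at 4–6 days of 5-min records, and bootstrap CIs at
1,999 resamples (fewer in hot loops where only the point estimate is
needed); these sizes were chosen so a full run completes in seconds on
one core while leaving Monte-Carlo error well below the tested
tolerances. Ties and degenerate inputs fail loudly (zero ranges,
empty night subsets, zero biomass, blank ≥ Fm) rather than returning
silent fallbacks. All file outputs are bit-reproducible for a given
config and seed on one platform.

## Known limitations

* The upper-anchor asymptote detection (the pixel-fraction curve on a
  global composite) is not reimplemented; the anchor is configuration.
* The solar geometry is a day-of-year approximation (no equation of
  time is needed because inputs are local solar time); accuracy is
  ~0.1–0.4°, adequate for cos(SZA) factors at low latitudes.
* NetCDF I/O uses the classic (NetCDF-3) format via the scipy backend.
* The sensitivity ratio compares slopes only; it does not attribute
  the model–observation mismatch to iron recycling, community
  restructuring, or any other mechanism.
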