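import numpy as np
import pandas as pd
import pytest

from conftest import make_spectrum
from ferrolux.ship_radiometry import (
    OC3_MODIS_DEFAULT,
    Spectrum,
    band_value,
    build_yield_series,
    compute_flh,
    compute_oc3_chl,
    local_solar_time,
    midday_extract,
    oc3_inverse_ratio,
    par_response,
)
from ferrolux.synthetic_data import ShipSimConfig, gen_ship_transect
from oracles import flh_oracle


class TestFLH:
    def test_linear_spectrum_is_zero(self):
        wl = np.arange(320.0, 951.0, 1.0)
        s = Spectrum(
            wavelengths=wl, l_w=0.003 * wl - 0.5,
            timestamp="2015-03-05", lat=0, lon=-140, par=1000,
        )
        assert compute_flh(s) == pytest.approx(0.0, abs=1e-12)

    def test_flat_baseline_peak(self):
        s = make_spectrum({667.0: 1.0, 678.0: 1.2, 748.0: 1.0})
        assert compute_flh(s) == pytest.approx(0.2, abs=1e-12)

    def test_sloped_baseline_example(self):
        s = make_spectrum({667.0: 2.0, 678.0: 1.95, 748.0: 1.19})
        assert compute_flh(s) == pytest.approx(0.060, abs=1e-3)
        assert compute_flh(s) == pytest.approx(
            flh_oracle(2.0, 1.95, 1.19), abs=1e-12
        )

    def test_missing_band_coverage_flagged(self):
        wl = np.arange(400.0, 700.0, 1.0)  # no 748 nm coverage
        s = Spectrum(
            wavelengths=wl, l_w=np.ones(wl.size),
            timestamp="2015-03-05", lat=0, lon=-140, par=1000,
        )
        assert np.isnan(compute_flh(s))

    def test_affine_perturbation_invariance(self, rng):
        wl = np.arange(600.0, 801.0, 1.0)
        for _ in range(20):
            base = rng.uniform(0.2, 2.0, size=wl.size)
            s = Spectrum(
                wavelengths=wl, l_w=base,
                timestamp="2015-03-05", lat=0, lon=-140, par=1000,
            )
            alpha, beta = rng.uniform(-1, 1), rng.uniform(-0.01, 0.01)
            s2 = Spectrum(
                wavelengths=wl, l_w=base + alpha + beta * wl,
                timestamp="2015-03-05", lat=0, lon=-140, par=1000,
            )
            ref = compute_flh(s)
            assert compute_flh(s2) == pytest.approx(
                ref, abs=1e-12 * max(1.0, abs(ref))
            )

    def test_band_value_interpolation_fallback(self):
        wl = np.array([600.0, 670.0, 690.0, 800.0])
        vals = np.array([1.0, 1.0, 3.0, 3.0])
        # 678 nm has no sample within +-2 nm: linear interpolation
        assert band_value(wl, vals, 678.0) == pytest.approx(1.8)


class TestOC3:
    def _spec_with_ratio(self, ratio):
        grid = np.array([400.0, 443.0, 488.0, 547.0, 667.0, 678.0, 748.0, 900.0])
        rrs = np.full(grid.size, 0.002)
        rrs[grid == 443.0] = 0.002 * ratio
        rrs[grid == 488.0] = 0.002 * ratio
        s = make_spectrum(grid=grid)
        s.r_rs = rrs
        return s

    def test_unit_ratio_gives_first_coefficient(self):
        chl = compute_oc3_chl(self._spec_with_ratio(1.0))
        assert chl == pytest.approx(10 ** OC3_MODIS_DEFAULT.coeffs[0])

    def test_monotone_decreasing_in_band_ratio(self):
        ratios = np.linspace(0.7, 8.0, 40)
        chls = [compute_oc3_chl(self._spec_with_ratio(r)) for r in ratios]
        assert np.all(np.diff(chls) < 0)

    def test_hand_evaluated_polynomial(self):
        r = np.log10(2.5)
        c = OC3_MODIS_DEFAULT.coeffs
        expected = 10 ** (
            c[0] + c[1] * r + c[2] * r**2 + c[3] * r**3 + c[4] * r**4
        )
        assert compute_oc3_chl(self._spec_with_ratio(2.5)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_nonpositive_reflectance_missing(self):
        s = self._spec_with_ratio(1.0)
        s.r_rs = np.zeros_like(s.r_rs)
        assert np.isnan(compute_oc3_chl(s))

    def test_inverse_ratio_round_trip(self):
        for chl in (0.1, 0.25, 0.4):
            r = oc3_inverse_ratio(chl)
            s = self._spec_with_ratio(10.0**r)
            assert compute_oc3_chl(s) == pytest.approx(chl, rel=1e-9)


class TestYieldSeries:
    def test_homogeneity_doubling_radiance(self):
        cfg = ShipSimConfig(n_days=1, noise_sd=0.0)
        spectra = gen_ship_transect(cfg)[:20]
        doubled = [
            Spectrum(
                wavelengths=s.wavelengths, l_w=2 * s.l_w, r_rs=s.r_rs,
                timestamp=s.timestamp, lat=s.lat, lon=s.lon, par=s.par,
            )
            for s in spectra
        ]
        a = build_yield_series(spectra)
        b = build_yield_series(doubled)
        # FLH doubles, OC3 ratio (hence chl) unchanged => F/Chl doubles
        np.testing.assert_allclose(b["flh"], 2 * a["flh"], rtol=1e-12)
        np.testing.assert_allclose(b["chl"], a["chl"], rtol=1e-12)
        np.testing.assert_allclose(b["fchl"], 2 * a["fchl"], rtol=1e-12)

    def test_rolling_smoothing_column(self):
        cfg = ShipSimConfig(n_days=1, noise_sd=0.05, seed=6)
        df = build_yield_series(
            gen_ship_transect(cfg), rolling_minutes=25.0
        )
        assert "fchl_smooth" in df.columns
        # smoothing reduces record-to-record scatter
        raw = df["fchl"].diff().abs().mean()
        smooth = df["fchl_smooth"].diff().abs().mean()
        assert smooth < raw

    def test_missing_chl_flags_yield(self):
        s = make_spectrum({667.0: 1.0, 678.0: 1.2, 748.0: 1.0})  # no r_rs
        df = build_yield_series([s])
        assert np.isnan(df["chl"].iloc[0]) and np.isnan(df["fchl"].iloc[0])

    def test_oc3_validation_regression_attached(self):
        cfg = ShipSimConfig(n_days=1, noise_sd=0.02, seed=2)
        spectra = gen_ship_transect(cfg)
        subset = spectra[::20]
        extracted = pd.DataFrame(
            {
                "timestamp": [s.timestamp for s in subset],
                "chl": 0.25
                * (1.0 + 0.08 * np.sin(np.arange(len(subset)))),
            }
        )
        df = build_yield_series(spectra, extracted_chl=extracted)
        assert "oc3_validation" in df.attrs
        assert df.attrs["oc3_validation"].n >= 3

    def test_regime_yield_ratio_recovered(self):
        cfg = ShipSimConfig(n_days=4, noise_sd=0.05, seed=11)
        df = build_yield_series(gen_ship_transect(cfg))
        midday = midday_extract(df)
        fe = midday[midday["lon"] < cfg.changepoint_lon]["fchl"].mean()
        n = midday[midday["lon"] >= cfg.changepoint_lon]["fchl"].mean()
        assert fe / n == pytest.approx(cfg.yield_ratio, rel=0.10)


class TestMiddayExtract:
    def _series(self, utc_hours, lon=-140.0):
        ts = [pd.Timestamp(f"2015-03-05T{h:02d}:{m:02d}:00")
              for h, m in utc_hours]
        return pd.DataFrame(
            {
                "timestamp": ts,
                "lon": lon,
                "fchl": 1.0,
                "par": 1000.0,
                "local_time": [local_solar_time(t, lon) for t in ts],
            }
        )

    def test_window_membership(self):
        # lon -140 => local = UTC - 9h20m; 22:50 UTC = 13:30 local
        df = self._series([(22, 50), (21, 19), (23, 59)])
        out = midday_extract(df)
        kept = out["local_time"].round(2).tolist()
        assert 13.5 in kept  # 13:30 kept
        assert not any(abs(v - 11.98) < 0.01 for v in kept)  # 11:59 dropped

    def test_all_night_series_warns_empty(self):
        df = self._series([(8, 0), (9, 0)])  # local ~22:40-23:40
        with pytest.warns(UserWarning, match="midday"):
            out = midday_extract(df)
        assert out.empty


class TestParResponse:
    def test_saturation_above_500(self):
        cfg = ShipSimConfig(n_days=4, noise_sd=0.03, seed=3)
        df = build_yield_series(gen_ship_transect(cfg))
        fe = df[df["lon"] < cfg.changepoint_lon]
        table, fit = par_response(fe)
        assert not fit.degenerate
        assert fit.par_at_fraction(0.95) > 500.0
        # empty PAR bins are simply absent from the table
        assert (table["n"] > 0).all()

    def test_constant_yield_degenerate(self):
        df = pd.DataFrame(
            {
                "par": np.linspace(50, 1950, 40),
                "fchl": 0.3,
            }
        )
        _, fit = par_response(df)
        assert fit.degenerate
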