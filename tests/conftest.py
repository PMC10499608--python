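import numpy as np
import pandas as pd
import pytest

from ferrolux.ship_radiometry import Spectrum


def make_spectrum(
    band_values: dict | None = None,
    rng: np.random.Generator | None = None,
    grid=None,
    **kwargs,
) -> Spectrum:
    """Spectrum on a sparse grid where band windows hold single samples.

    ``band_values`` pins the radiance at specific wavelengths (grid
    points are spaced so the ±2 nm band windows contain exactly that
    sample); elsewhere the spectrum is interpolated.
    """
    if grid is None:
        grid = np.array([400.0, 550.0, 640.0, 667.0, 678.0, 720.0, 748.0, 900.0])
    if band_values is None:
        band_values = {}
    if rng is not None:
        values = rng.uniform(0.1, 2.0, size=grid.size)
    else:
        values = np.full(grid.size, 1.0)
    for wl, v in band_values.items():
        idx = np.argmin(np.abs(grid - wl))
        assert abs(grid[idx] - wl) < 1e-9, f"no grid point at {wl}"
        values[idx] = v
    defaults = dict(
        timestamp=pd.Timestamp("2015-03-05T20:00:00"),
        lat=0.0,
        lon=-140.0,
        par=1500.0,
    )
    defaults.update(kwargs)
    return Spectrum(wavelengths=grid, l_w=values, **defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
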