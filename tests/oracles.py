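"""Independent reference implementations used only by the tests.

These are deliberately written against different formulations than the
package code: the ranged-major-axis oracle extracts the principal axis
by eigen-decomposition instead of the closed-form root, and the solar
zenith oracle transcribes the NOAA solar-position algorithm
(mean-obliquity + apparent solar longitude declination) instead of the
Spencer day-of-year series.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def rma_oracle(x, y):
    """Ranged-major-axis slope/intercept via principal-axis eigenvector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u = (x - x.min()) / np.ptp(x)
    v = (y - y.min()) / np.ptp(y)
    cov = np.cov(u, v)
    w, vec = np.linalg.eigh(cov)
    major = vec[:, np.argmax(w)]
    slope_ranged = major[1] / major[0]
    slope = slope_ranged * np.ptp(y) / np.ptp(x)
    intercept = y.mean() - slope * x.mean()
    return slope, intercept


def flh_oracle(l667, l678, l748):
    """FLH as peak radiance minus an interpolated linear baseline."""
    baseline = np.interp(678.0, [667.0, 748.0], [l667, l748])
    return l678 - baseline


def noaa_declination(date) -> float:
    """Solar declination (degrees) per the NOAA solar position algorithm."""
    jd = pd.Timestamp(date).to_julian_date()
    T = (jd - 2451545.0) / 36525.0
    L0 = (280.46646 + 36000.76983 * T + 0.0003032 * T**2) % 360.0
    M = 357.52911 + 35999.05029 * T - 0.0001537 * T**2
    Mr = np.radians(M)
    C = (
        (1.914602 - 0.004817 * T - 0.000014 * T**2) * np.sin(Mr)
        + (0.019993 - 0.000101 * T) * np.sin(2 * Mr)
        + 0.000289 * np.sin(3 * Mr)
    )
    true_long = L0 + C
    omega = 125.04 - 1934.136 * T
    lam = true_long - 0.00569 - 0.00478 * np.sin(np.radians(omega))
    eps0 = (
        23.0 + 26.0 / 60.0 + 21.448 / 3600.0
        - (46.815 * T + 0.00059 * T**2 - 0.001813 * T**3) / 3600.0
    )
    eps = eps0 + 0.00256 * np.cos(np.radians(omega))
    decl = np.arcsin(np.sin(np.radians(eps)) * np.sin(np.radians(lam)))
    return float(np.degrees(decl))


def noaa_solar_zenith(lat, date, local_solar_time) -> float:
    """Zenith angle from the NOAA declination and the hour angle."""
    decl = np.radians(noaa_declination(date))
    h = np.radians(15.0 * (local_solar_time - 12.0))
    latr = np.radians(lat)
    cosz = np.sin(latr) * np.sin(decl) + np.cos(latr) * np.cos(decl) * np.cos(h)
    return float(np.degrees(np.arccos(np.clip(cosz, -1.0, 1.0))))


def welch_ttest_oracle(x, y):
    """Textbook Welch t and two-sided p (Welch–Satterthwaite df)."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, p


def oneway_anova_oracle(groups):
    """Textbook one-way ANOVA F and p from explicit sums of squares."""
    from scipy.stats import f as fdist

    arrays = [np.asarray(g, dtype=float) for g in groups.values()]
    grand = np.concatenate(arrays).mean()
    k = len(arrays)
    n = sum(a.size for a in arrays)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = fdist.sf(f, k - 1, n - k)
    return f, p


def tukey_reject_oracle(groups, alpha=0.05):
    """Tukey HSD reject flags from the studentized-range critical value.

    Valid for balanced designs.
    """
    from scipy.stats import studentized_range

    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    sizes = {a.size for a in arrays.values()}
    assert len(sizes) == 1, "oracle assumes a balanced design"
    n_per = sizes.pop()
    k = len(arrays)
    df_w = sum(a.size for a in arrays.values()) - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_w
    q_crit = studentized_range.ppf(1 - alpha, k, df_w)
    hsd = q_crit * np.sqrt(msw / n_per)
    labels = list(arrays)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(arrays[labels[i]].mean() - arrays[labels[j]].mean())
            out[(labels[i], labels[j])] = diff > hsd
    return out
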