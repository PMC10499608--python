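"""Statistical primitives shared by the pipeline stages.

The central estimator is the ranged-major-axis (RMA) type II regression:
both variables are range-transformed to [0, 1], a major-axis (principal
axis) slope is computed on the transformed data, and the slope is
back-transformed by the ratio of the raw ranges, with the line forced
through the bivariate means.  Type II regression is appropriate whenever
both variables carry comparable error, as is the case for satellite
anomaly series regressed on each other.

Also provided: a saturating tanh light-response fit, one-way ANOVA with
Tukey's HSD, an unpaired t-test, and a time-based centred rolling mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "InvalidInputError",
    "FitFailureError",
    "RMAResults",
    "RangedMajorAxis",
    "rma_regression",
    "TanhFitResults",
    "TanhLightResponse",
    "fit_tanh_response",
    "AnovaTukeyResults",
    "anova_tukey",
    "ttest_unpaired",
    "rolling_mean",
]


class InvalidInputError(ValueError):
    """Raised when data violate an estimator's preconditions."""


class FitFailureError(RuntimeError):
    """Raised when an iterative fit does not converge.

    Carries ``last_iterate`` — the parameter vector at the point of
    failure — so callers can inspect or restart.
    """

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


# ---------------------------------------------------------------------------
# Ranged major axis (type II) regression
# ---------------------------------------------------------------------------


@dataclass
class RMAResults:
    """Results of a type II (ranged major axis) regression.

    Attributes
    ----------
    slope, intercept : float
        Back-transformed RMA line, in response units per predictor unit.
    r_squared : float
        Squared Pearson correlation of the raw pairs.
    p_value : float
        Two-tailed significance of the association (Pearson t-test, or a
        permutation test when requested at fit time).
    slope_ci_low, slope_ci_high : float
        Percentile-bootstrap confidence bounds on the slope.
    n : int
        Number of pairs used.
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_ci_low: float
    slope_ci_high: float
    n: int
    method: str = "ranged_major_axis"
    ci_level: float = 0.95

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def summary(self) -> str:
        lines = [
            f"Type II regression ({self.method}), n = {self.n}",
            f"  slope     {self.slope: .6g}  "
            f"[{self.slope_ci_low:.6g}, {self.slope_ci_high:.6g}] "
            f"({100 * self.ci_level:.0f}% bootstrap CI)",
            f"  intercept {self.intercept: .6g}",
            f"  R^2       {self.r_squared: .4f}   P = {self.p_value:.3g}",
        ]
        return "\n".join(lines)


def _validate_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InvalidInputError(
            f"x and y lengths differ ({x.size} vs {y.size})"
        )
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InvalidInputError("need at least 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError(
            "zero range in x or y: ranging transform undefined"
        )
    return x, y


def _rma_slope(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ranged-major-axis slope, vectorised over leading axes.

    ``x`` and ``y`` have shape (..., n); pairs along the last axis.
    Resamples whose x- or y-range collapses to zero return NaN.
    """
    xmin = x.min(axis=-1, keepdims=True)
    ymin = y.min(axis=-1, keepdims=True)
    rx = x.max(axis=-1, keepdims=True) - xmin
    ry = y.max(axis=-1, keepdims=True) - ymin
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (x - xmin) / rx
        v = (y - ymin) / ry
        mu = u.mean(axis=-1, keepdims=True)
        mv = v.mean(axis=-1, keepdims=True)
        suu = ((u - mu) ** 2).mean(axis=-1)
        svv = ((v - mv) ** 2).mean(axis=-1)
        suv = ((u - mu) * (v - mv)).mean(axis=-1)
        # major-axis slope on the ranged variables: eigenvector of the
        # leading principal axis, via the closed-form root
        disc = np.sqrt((svv - suu) ** 2 + 4.0 * suv**2)
        b_ranged = np.where(suv != 0, (svv - suu + disc) / (2.0 * suv), np.nan)
        slope = b_ranged * (ry / rx).squeeze(-1)
    return slope


class RangedMajorAxis:
    """Type II regression model of ``y`` on ``x`` (ranged major axis).

    Both variables are range-transformed to [0, 1] before the major-axis
    slope is extracted, making the estimator symmetric in the two error
    structures and insensitive to the variables' units.

    Parameters
    ----------
    y, x : array_like
        Paired observations.  Pairs with non-finite entries are dropped.
    """

    def __init__(self, y, x):
        self.x, self.y = _validate_pairs(x, y)
        self.nobs = self.x.size

    def fit(
        self,
        n_boot: int = 1999,
        seed: int = 0,
        n_permutations: int = 0,
        ci_level: float = 0.95,
    ) -> RMAResults:
        x, y = self.x, self.y
        slope = float(_rma_slope(x, y))
        intercept = float(y.mean() - slope * x.mean())
        r, p_param = stats.pearsonr(x, y)

        rng = np.random.default_rng(seed)
        if n_permutations > 0:
            # permutation p: shuffle y, compare |r|
            perm = np.array(
                [
                    abs(stats.pearsonr(x, rng.permutation(y))[0])
                    for _ in range(n_permutations)
                ]
            )
            p_value = (1.0 + np.sum(perm >= abs(r))) / (1.0 + n_permutations)
        else:
            p_value = float(p_param)

        if n_boot > 0:
            idx = rng.integers(0, x.size, size=(n_boot, x.size))
            bs = _rma_slope(x[idx], y[idx])
            bs = bs[np.isfinite(bs)]
            alpha = 1.0 - ci_level
            lo, hi = np.percentile(bs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            # the point estimate always lies inside the reported interval
            lo, hi = min(lo, slope), max(hi, slope)
        else:
            lo = hi = slope

        return RMAResults(
            slope=slope,
            intercept=intercept,
            r_squared=float(r**2),
            p_value=float(p_value),
            slope_ci_low=float(lo),
            slope_ci_high=float(hi),
            n=x.size,
            ci_level=ci_level,
        )


def rma_regression(
    x, y, n_permutations: int = 0, seed: int = 0, n_boot: int = 1999
) -> RMAResults:
    """Convenience wrapper: fit a :class:`RangedMajorAxis` of y on x."""
    return RangedMajorAxis(y, x).fit(
        n_boot=n_boot, seed=seed, n_permutations=n_permutations
    )


# ---------------------------------------------------------------------------
# Saturating tanh light response
# ---------------------------------------------------------------------------


@dataclass
class TanhFitResults:
    """Fitted saturating light response ``y = a * tanh(b * PAR / a)``.

    ``a`` is the light-saturated plateau (units of the fitted yield) and
    ``b`` the light-limited initial slope (yield per PAR unit); the curve
    derivative at PAR = 0 equals ``b`` and the value tends to ``a`` as
    PAR grows.
    """

    a: float
    b: float
    residual_rms: float
    converged: bool = True
    degenerate: bool = False

    def predict(self, par):
        par = np.asarray(par, dtype=float)
        if self.degenerate or self.b == 0:
            return np.full_like(par, self.a, dtype=float)
        return self.a * np.tanh(self.b * par / self.a)

    def par_at_fraction(self, frac: float = 0.95) -> float:
        """PAR at which the fitted curve reaches ``frac`` of the plateau."""
        if not 0 < frac < 1:
            raise InvalidInputError("frac must be in (0, 1)")
        if self.degenerate or self.b <= 0:
            return np.nan
        return float(self.a / self.b * np.arctanh(frac))

    def summary(self) -> str:
        return (
            f"tanh light response: a = {self.a:.4g} (plateau), "
            f"b = {self.b:.4g} (initial slope), "
            f"residual rms = {self.residual_rms:.3g}"
        )


def _tanh_model(par, a, b):
    return a * np.tanh(b * par / a)


class TanhLightResponse:
    """Least-squares model for a saturating fluorescence–PAR response."""

    def __init__(self, par, yield_values):
        par = np.asarray(par, dtype=float).ravel()
        y = np.asarray(yield_values, dtype=float).ravel()
        if par.size != y.size:
            raise InvalidInputError("par and yield lengths differ")
        ok = np.isfinite(par) & np.isfinite(y)
        self.par, self.y = par[ok], y[ok]
        if self.par.size < 5:
            raise InvalidInputError("need at least 5 points for the tanh fit")

    def fit(self, init: tuple[float, float] | None = None) -> TanhFitResults:
        par, y = self.par, self.y
        span = float(np.ptp(y))
        top = float(np.max(np.abs(y)))
        if top == 0 or span < 1e-12 * max(top, 1.0):
            # constant response: no saturation structure to fit
            return TanhFitResults(
                a=float(np.mean(y)), b=0.0, residual_rms=float(np.std(y)),
                converged=False, degenerate=True,
            )
        if init is None:
            a0 = float(np.percentile(y, 90))
            # initial slope from the lowest-PAR third
            lo = par <= np.percentile(par, 33)
            with np.errstate(divide="ignore", invalid="ignore"):
                b0 = float(np.nanmedian(y[lo] / np.where(par[lo] > 0, par[lo], np.nan)))
            if not np.isfinite(b0) or b0 <= 0:
                b0 = a0 / max(par.max(), 1.0)
            init = (max(a0, 1e-12), max(b0, 1e-12))
        try:
            popt, _ = optimize.curve_fit(
                _tanh_model, par, y, p0=init,
                bounds=([1e-15, 1e-15], [np.inf, np.inf]),
                maxfev=10000,
            )
        except RuntimeError as exc:
            raise FitFailureError(
                f"tanh response fit did not converge: {exc}", last_iterate=init
            ) from exc
        a, b = float(popt[0]), float(popt[1])
        resid = y - _tanh_model(par, a, b)
        return TanhFitResults(
            a=a, b=b, residual_rms=float(np.sqrt(np.mean(resid**2)))
        )


def fit_tanh_response(par, yield_values, init=None) -> TanhFitResults:
    return TanhLightResponse(par, yield_values).fit(init=init)


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD, t-test, rolling mean
# ---------------------------------------------------------------------------


@dataclass
class AnovaTukeyResults:
    f_statistic: float
    p_value: float
    alpha: float
    pairs: pd.DataFrame = field(repr=False)

    def significant_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["reject"]]

    def summary(self) -> str:
        head = (
            f"One-way ANOVA: F = {self.f_statistic:.4g}, "
            f"P = {self.p_value:.3g} (alpha = {self.alpha})"
        )
        return head + "\n" + self.pairs.to_string(index=False)


def anova_tukey(groups: dict, alpha: float = 0.05) -> AnovaTukeyResults:
    """One-way ANOVA across labelled groups, then Tukey's HSD per pair.

    Parameters
    ----------
    groups : mapping label -> array_like of replicate values
    alpha : family-wise error rate for the HSD flags
    """
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    for label, arr in arrays.items():
        if arr.size < 2:
            raise InvalidInputError(
                f"group {label!r} has fewer than 2 replicates"
            )
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate(
        [np.repeat(k, v.size) for k, v in arrays.items()]
    )
    if np.ptp(values) == 0:
        # all observations identical: F = 0 by convention, nothing significant
        labs = list(arrays)
        rows = [
            {"group1": labs[i], "group2": labs[j], "meandiff": 0.0,
             "p_adj": 1.0, "lower": 0.0, "upper": 0.0, "reject": False}
            for i in range(len(labs)) for j in range(i + 1, len(labs))
        ]
        return AnovaTukeyResults(0.0, 1.0, alpha, pd.DataFrame(rows))
    f_stat, p = stats.f_oneway(*arrays.values())
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    ).rename(columns={"p-adj": "p_adj"})
    pairs["reject"] = pairs["reject"].astype(bool)
    return AnovaTukeyResults(float(f_stat), float(p), alpha, pairs)


def ttest_unpaired(x, y, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided unpaired t-test (Welch by default).

    Degenerate inputs (both samples constant with equal means) return
    ``(0.0, 1.0)`` rather than NaN.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise InvalidInputError("each sample needs at least 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    if not np.isfinite(p):
        p = 1.0
    return float(t), float(p)


def rolling_mean(times, values, window) -> np.ndarray:
    """Centred, time-based rolling mean with inclusive endpoints.

    For each timestamp t the mean is taken over samples with
    ``|t_i - t| <= window / 2``, ignoring NaN.  ``window`` is a
    ``pandas.Timedelta``, anything it accepts, or minutes as a number.
    """
    times = pd.DatetimeIndex(times)
    if not times.is_monotonic_increasing:
        raise InvalidInputError("timestamps must be monotone increasing")
    values = np.asarray(values, dtype=float).ravel()
    if times.size != values.size:
        raise InvalidInputError("times and values lengths differ")
    if isinstance(window, (int, float)):
        window = pd.Timedelta(minutes=window)
    else:
        window = pd.Timedelta(window)
    half = window / 2
    t = times.asi8
    h = int(half.value)
    left = np.searchsorted(t, t - h, side="left")
    right = np.searchsorted(t, t + h, side="right")
    csum = np.concatenate([[0.0], np.nancumsum(values)])
    cnt = np.concatenate([[0], np.cumsum(np.isfinite(values))])
    num = csum[right] - csum[left]
    den = cnt[right] - cnt[left]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out
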