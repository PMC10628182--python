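"""Per-target-color response histograms and four-parameter Gaussian fits.

For each target color the fraction of responses landing on each of the 64
wheel colors is computed per session, averaged, and circularly shifted so the
target sits at position 33.  The re-centered histogram is then characterized
by nonlinear least squares with

    y = a * exp(-((x - b) / c)^2) + d

where a is the peak response fraction, b the peak position (33 = on target),
c the peak width and d the intercept (a measure of random responding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .wheel import ColorWheelSpec

CENTER_POSITION = 33  # target position after the circular shift (1-based)


def _gauss(x, a, b, c, d):
    return a * np.exp(-(((x - b) / c) ** 2)) + d


def per_color_histogram(
    table: pd.DataFrame,
    target_idx: int,
    wheel: ColorWheelSpec = ColorWheelSpec(),
    by_session: bool = True,
) -> np.ndarray:
    """Response-fraction histogram for one target color, target re-centered.

    Per session the response counts over the 64 colors are normalized to sum
    to one, then averaged across sessions, then circularly shifted so the
    target occupies position ``CENTER_POSITION``.
    """
    n = wheel.n_colors
    sub = table[table["target_idx"] == target_idx]
    if len(sub) == 0:
        raise ValueError(f"no trials with target color {target_idx}")
    groups = sub.groupby("session_id") if by_session else [(None, sub)]
    fractions = []
    for _, g in groups:
        counts = np.bincount(g["response_idx"].to_numpy(int), minlength=n + 1)[1:]
        fractions.append(counts / counts.sum())
    hist = np.mean(fractions, axis=0)
    # shift so the target index lands on CENTER_POSITION (1-based)
    return np.roll(hist, CENTER_POSITION - target_idx)


@dataclass
class ColorTuningFit:
    """Coefficients of the per-color Gaussian characterization."""

    amplitude: float
    center: float
    width: float
    intercept: float
    adj_r2: float
    converged: bool

    @property
    def center_offset_deg(self) -> float:
        """Signed peak shift from the target in degrees of the color wheel."""
        return (self.center - CENTER_POSITION) * 360.0 / 64.0


class GaussianTuning(BaseEstimator):
    """Nonlinear least-squares Gaussian fit of a re-centered color histogram.

    Starting values follow the analysis convention: a = 1, b = 33 (the
    shifted target position), c = 1, d = mean response fraction over the 30
    farthermost colors (positions 1-15 and 50-64).  Amplitude, width and
    intercept are constrained non-negative.

    Attributes (after ``fit``): ``amplitude_``, ``center_``, ``width_``,
    ``intercept_``, ``adj_r2_``, ``converged_``.
    """

    def __init__(self, maxfev: int = 10000):
        self.maxfev = maxfev

    def fit(self, histogram):
        y = np.asarray(histogram, dtype=float).ravel()
        n = len(y)
        x = np.arange(1, n + 1, dtype=float)
        far = np.r_[y[:15], y[49:]] if n == 64 else y[np.abs(x - (n // 2 + 1)) > n // 4]
        p0 = [1.0, float(n // 2 + 1), 1.0, float(np.mean(far))]
        bounds = ([0.0, -np.inf, 1e-6, 0.0], [np.inf, np.inf, np.inf, np.inf])
        try:
            popt, _ = curve_fit(_gauss, x, y, p0=p0, bounds=bounds, maxfev=self.maxfev)
            converged = True
        except RuntimeError:
            popt, converged = p0, False
        resid = y - _gauss(x, *popt)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        p = 4
        if ss_tot > 0 and n > p + 1:
            r2 = 1 - ss_res / ss_tot
            adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
        else:
            adj = 0.0  # zero-variance histogram: no variance to explain
        self.amplitude_, self.center_, self.width_, self.intercept_ = map(float, popt)
        self.adj_r2_ = adj
        self.converged_ = converged
        return self

    def result_(self) -> ColorTuningFit:
        return ColorTuningFit(
            self.amplitude_, self.center_, self.width_, self.intercept_,
            self.adj_r2_, self.converged_,
        )


def fit_color_tuning(histogram, **kwargs) -> ColorTuningFit:
    """Functional wrapper over :class:`GaussianTuning`."""
    return GaussianTuning(**kwargs).fit(histogram).result_()


def color_tuning_table(table: pd.DataFrame, wheel: ColorWheelSpec = ColorWheelSpec()) -> pd.DataFrame:
    """Gaussian tuning coefficients for every target color (64-row table)."""
    rows = []
    for color in range(1, wheel.n_colors + 1):
        hist = per_color_histogram(table, color, wheel)
        fit = fit_color_tuning(hist)
        rows.append(
            {
                "color": color,
                "amplitude": fit.amplitude,
                "center": fit.center,
                "center_offset_deg": fit.center_offset_deg,
                "width": fit.width,
                "intercept": fit.intercept,
                "adj_r2": fit.adj_r2,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
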