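"""Shared regression utilities.

Count time-series are smoothed with a three-parameter logistic
f(t) = A / (1 + exp(-(t - t0)/tau)); tau may be negative so decreasing
series (a shrinking progenitor pool) fit with the same family.  Linear
fits report the slope uncertainty by refitting the data shifted by plus
and minus one standard error and halving the slope difference — the
scheme used for cumulative-curve analysis — rather than the OLS standard
error.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import FitFailureError, SingularFitError

__all__ = ["SigmoidFit", "sigmoid_fit", "linear_fit_with_band", "propagate_T_error"]


def _logistic(t, A, t0, tau):
    return A / (1.0 + np.exp(-(t - t0) / tau))


@dataclass
class SigmoidFit:
    """Fitted three-parameter logistic, evaluable with its derivative."""

    A: float
    t0: float
    tau: float
    rss: float
    n: int

    def __call__(self, t):
        return _logistic(np.asarray(t, dtype=float), self.A, self.t0, self.tau)

    def derivative(self, t):
        t = np.asarray(t, dtype=float)
        e = np.exp(-(t - self.t0) / self.tau)
        return self.A * e / (self.tau * (1.0 + e) ** 2)

    @property
    def params(self) -> tuple[float, float, float]:
        return self.A, self.t0, self.tau


def _starting_points(t, y, rng):
    span = float(t.max() - t.min()) or 1.0
    ymax = float(np.max(np.abs(y))) or 1.0
    increasing = y[-1] >= y[0]
    # half-max crossing for t0
    half = 0.5 * float(y.max() if increasing else y[0])
    idx = int(np.argmin(np.abs(y - half)))
    t0 = float(t[idx])
    tau0 = span / 10.0 if increasing else -span / 10.0
    starts = [
        (ymax, t0, tau0),
        # near-linear regime: huge amplitude, huge tau
        (10.0 * ymax, float(t.mean()) + 5.0 * span, 5.0 * span),
        (ymax, float(t.mean()), span / 4.0 if increasing else -span / 4.0),
    ]
    for _ in range(5):
        jitter = rng.uniform(0.7, 1.3, size=3)
        starts.append((ymax * jitter[0], t0 * jitter[1], tau0 * jitter[2]))
    return starts


def sigmoid_fit(times, counts, ses=None, seed: int = 0) -> SigmoidFit:
    """Least-squares logistic fit with multi-start initialization.

    ``ses``, when given, weight the residuals (points with zero SE are
    given the median positive SE to avoid infinite weight).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(t) < 4:
        raise FitFailureError("sigmoid fit needs at least 4 points")
    sigma = None
    if ses is not None:
        sigma = np.asarray(ses, dtype=float).copy()
        pos = sigma[sigma > 0]
        sigma[sigma <= 0] = np.median(pos) if len(pos) else 1.0
    rng = np.random.default_rng(seed)
    best = None
    errors = []
    for p0 in _starting_points(t, y, rng):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                popt, _ = curve_fit(_logistic, t, y, p0=p0, sigma=sigma, maxfev=20000)
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - scipy detail
            errors.append(str(exc))
            continue
        if popt[2] == 0 or not np.all(np.isfinite(popt)):
            continue
        rss = float(np.sum((y - _logistic(t, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise FitFailureError(f"sigmoid fit did not converge from any start: {errors}")
    rss, (A, t0, tau) = best
    return SigmoidFit(float(A), float(t0), float(tau), rss, len(t))


def linear_fit_with_band(x, y, y_se=None) -> tuple[float, float, float]:
    """OLS line plus the +/-SE-refit slope uncertainty.

    Returns (slope, intercept, slope_se) where slope_se is half the
    difference between the slopes fitted to y + se and y - se.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise SingularFitError("need at least 2 points")
    if np.ptp(x) == 0:
        raise SingularFitError("all x values identical")
    slope, intercept = np.polyfit(x, y, 1)
    if y_se is None:
        return float(slope), float(intercept), 0.0
    se = np.asarray(y_se, dtype=float)
    s_hi = np.polyfit(x, y + se, 1)[0]
    s_lo = np.polyfit(x, y - se, 1)[0]
    return float(slope), float(intercept), float(abs(s_hi - s_lo) / 2.0)


def propagate_T_error(gamma: float, gamma_se: float, slope: float, slope_se: float) -> float:
    """Quadrature propagation of T = gamma / slope."""
    return float(
        np.sqrt((gamma_se / slope) ** 2 + (gamma * slope_se / slope**2) ** 2)
    )
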