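"""The four cell-cycle / mode-of-division estimation methods.

C1 — single cumulative curve: the labeled-progenitor fraction rises
linearly with exposure (slope gamma/T) and plateaus at the growth
fraction gamma, so T = gamma / slope.

C2 — dual cumulative curve: with the first label saturated, the
double-positive fraction obeys the same labeling-index law in the second
label's exposure; the intercept gamma*T_S/T additionally yields T_S.

PC — pulse-chase: the pulse-labeled S-phase cohort re-enters S one full
cycle later, so the double-positive fraction peaks at chase ≈ T.

BP — branching-process inversion of the population balance over time
windows [t0, t]:

    pp - dd = (ΔP + Φ) / (ΔP + ΔD + Φ)
    T       = γ̄ · I / (ΔP + ΔD + Φ)

with ΔP, ΔD the count changes, I = ∫ P dt, Φ = ∫ ∅_P(t) P dt the death
mass and γ̄ the window-averaged growth fraction.  These invert the
forward model dP/dt = (ppdd·γ/T − ∅_P)·P, dD/dt = (1−ppdd)·γ·P/T exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .cellsim import CountsTimeSeries
from .curvefit import linear_fit_with_band, propagate_T_error, sigmoid_fit
from .errors import (
    EstimationError,
    InsufficientDataError,
    InvalidParameterError,
    PeakNotBracketedError,
)
from .labeling import CumulativeCurve

__all__ = [
    "C1Result",
    "C2Result",
    "PCResult",
    "BranchingEstimate",
    "ModeRates",
    "c1_fit",
    "c2_fit",
    "pc_fit",
    "bp_estimate",
    "propagate_ci50",
    "decompose_modes",
]


@dataclass(frozen=True)
class C1Result:
    T_hat: float
    gamma_hat: float
    slope: float
    slope_se: float
    gamma_se: float
    T_se: float


@dataclass(frozen=True)
class C2Result:
    T_hat: float
    T_S_hat: float
    gamma_hat: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class PCResult:
    T_hat: float
    T_S_hat: float
    peak_fraction: float


@dataclass
class BranchingEstimate:
    """Time-resolved mode and rate of division with 50% confidence bands.

    Values are attached to window midpoints; windows where the division
    mass ΔP + ΔD + Φ was non-positive are masked (NaN), not extrapolated.
    """

    grid: np.ndarray  # window midpoints (hours)
    windows: np.ndarray  # (k, 2) window edges
    ppdd_hat: np.ndarray
    T_hat: np.ndarray
    ppdd_lo: np.ndarray | None = None
    ppdd_hi: np.ndarray | None = None
    T_lo: np.ndarray | None = None
    T_hi: np.ndarray | None = None

    def mean_T(self) -> float:
        """Average of the defined window estimates of T."""
        vals = self.T_hat[np.isfinite(self.T_hat)]
        if len(vals) == 0:
            raise EstimationError("no window produced a defined T estimate")
        return float(np.mean(vals))

    def mean_ppdd(self) -> float:
        vals = self.ppdd_hat[np.isfinite(self.ppdd_hat)]
        if len(vals) == 0:
            raise EstimationError("no window produced a defined pp-dd estimate")
        return float(np.mean(vals))

    def to_frame(self):
        import pandas as pd

        d = {
            "time_h": self.grid,
            "ppdd": self.ppdd_hat,
            "T": self.T_hat,
        }
        for name in ("ppdd_lo", "ppdd_hi", "T_lo", "T_hi"):
            v = getattr(self, name)
            if v is not None:
                d[name] = v
        return pd.DataFrame(d)


@dataclass(frozen=True)
class ModeRates:
    pp: float
    pd: float
    dd: float

    @property
    def ppdd(self) -> float:
        return self.pp - self.dd


# ---------------------------------------------------------------------------
# cumulative methods


def _plateau_points(curve: CumulativeCurve, n_late: int) -> np.ndarray:
    return curve.fraction[-n_late:]


def c1_fit(curve: CumulativeCurve, n_early: int = 4, n_late: int = 4) -> C1Result:
    """Single cumulative-curve estimate.

    OLS on the first ``n_early`` points gives the slope; the mean of the
    last ``n_late`` fractions gives the growth fraction; T = gamma/slope.
    Slope error follows the ±SE-refit scheme and propagates into T in
    quadrature.
    """
    if len(curve) < n_early + 1:
        raise InsufficientDataError(
            f"cumulative curve has {len(curve)} points; need more than n_early={n_early}"
        )
    x = curve.exposure_h[:n_early]
    y = curve.fraction[:n_early]
    se = curve.se[:n_early]
    slope, _, slope_se = linear_fit_with_band(x, y, se)
    if slope <= 1e-9:
        raise EstimationError(f"non-positive early slope ({slope:.4g}/h); no labeling uptake")
    late = _plateau_points(curve, n_late)
    gamma_hat = float(np.mean(late))
    gamma_se = float(np.std(late, ddof=1) / np.sqrt(len(late))) if len(late) > 1 else 0.0
    if gamma_hat > 1.0:
        warnings.warn("plateau estimate above 1; clipping to 1", stacklevel=2)
        gamma_hat = 1.0
    T_hat = gamma_hat / slope
    T_se = propagate_T_error(gamma_hat, gamma_se, slope, slope_se)
    return C1Result(T_hat, gamma_hat, slope, slope_se, gamma_se, T_se)


def c2_fit(
    curve: CumulativeCurve,
    n_early: int = 4,
    n_late: int = 4,
    gamma: float | None = None,
) -> C2Result:
    """Dual cumulative-curve estimate of (T, T_S).

    The double-positive fraction against second-label exposure δ follows
    f(δ) = γ(T_S + δ)/T before its plateau, so T = γ/slope and
    T_S = intercept·T/γ.  γ comes from the curve's plateau when reached,
    otherwise it must be supplied.
    """
    if len(curve) < 3:
        raise InsufficientDataError("dual cumulative fit needs at least 3 points")
    n_early = min(n_early, len(curve))
    x = curve.exposure_h[:n_early]
    y = curve.fraction[:n_early]
    se = curve.se[:n_early]
    slope, intercept, _ = linear_fit_with_band(x, y, se)
    if slope <= 1e-9:
        raise EstimationError(f"non-positive early slope ({slope:.4g}/h)")
    if gamma is None:
        gamma_hat = float(np.mean(_plateau_points(curve, n_late)))
        gamma_hat = min(gamma_hat, 1.0)
    else:
        gamma_hat = float(gamma)
    T_hat = gamma_hat / slope
    T_S_hat = max(0.0, intercept * T_hat / gamma_hat) if gamma_hat > 0 else 0.0
    return C2Result(T_hat, T_S_hat, gamma_hat, slope, float(intercept))


# ---------------------------------------------------------------------------
# pulse-chase


def _quadratic_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through three points (falls back to the
    middle point for degenerate curvature)."""
    a, b, c = np.polyfit(x, y, 2)
    if a >= 0:
        return float(x[1]), float(y[1])
    xv = -b / (2 * a)
    if not x[0] <= xv <= x[2]:
        return float(x[1]), float(y[1])
    return float(xv), float(c - b**2 / (4 * a))


def pc_fit(curve: CumulativeCurve) -> PCResult:
    """Pulse-chase estimate: T from the chase time of the re-entry peak.

    The raw curve starts high (the pulsed cohort is still in S), falls to
    a trough while the cohort transits G2/M and G1, then rises to the
    re-entry peak at chase ≈ T.  The peak is located after the first
    trough and refined by quadratic interpolation through its three
    nearest points.  T_S is read from the rising flank as
    (peak − trough) / rising slope.
    """
    x = curve.exposure_h
    y = curve.fraction
    if len(x) < 4:
        raise InsufficientDataError("pulse-chase fit needs at least 4 chase points")
    if np.all(y <= 0):
        raise EstimationError("double-positive fraction identically zero; no S re-entry")
    i_min = int(np.argmin(y[: max(2, len(y) // 2)]))
    i_max = i_min + int(np.argmax(y[i_min:]))
    if i_max >= len(y) - 1:
        raise PeakNotBracketedError(
            "re-entry maximum at the last chase point; extend the chase window"
        )
    if i_max == 0:
        raise EstimationError("curve is monotonically decreasing; no re-entry peak")
    if i_max == i_min or y[i_max] <= y[i_min]:
        raise EstimationError("no re-entry peak rises above the post-pulse trough")
    T_hat, peak_val = _quadratic_vertex(x[i_max - 1 : i_max + 2], y[i_max - 1 : i_max + 2])
    # rising flank: the steep 10-90% band of the rise (the flat trough
    # bottom and the rounding near the peak would both dilute the slope)
    rise_amp = peak_val - y[i_min]
    flank = np.arange(i_min, i_max + 1)
    in_band = (y[flank] >= y[i_min] + 0.1 * rise_amp) & (
        y[flank] <= y[i_min] + 0.9 * rise_amp
    )
    flank = flank[in_band] if in_band.sum() >= 2 else np.arange(i_min, i_max + 1)
    slope, _, _ = linear_fit_with_band(x[flank], y[flank])
    T_S_hat = float(rise_amp / slope) if slope > 0 else float("nan")
    return PCResult(float(T_hat), T_S_hat, float(peak_val))


# ---------------------------------------------------------------------------
# branching process


def _as_callables(
    counts: CountsTimeSeries, fit: str, seed: int
) -> tuple[Callable, Callable, float, float]:
    t = counts.time
    P = counts.column("P")
    D = counts.column("D")
    if fit == "sigmoid":
        fP = sigmoid_fit(t, P, seed=seed)
        fD = sigmoid_fit(t, D, seed=seed + 1)
        return fP, fD, float(t[0]), float(t[-1])
    if fit == "none":
        fP = lambda x: np.interp(x, t, P)  # noqa: E731
        fD = lambda x: np.interp(x, t, D)  # noqa: E731
        return fP, fD, float(t[0]), float(t[-1])
    raise InvalidParameterError(f"unknown fit mode {fit!r}")


def bp_estimate(
    counts: CountsTimeSeries | tuple[Callable, Callable],
    gamma: Callable[[float], float] | float = 1.0,
    apoptosis_rate: Callable[[float], float] | float = 0.0,
    grid: Sequence[float] | None = None,
    fit: str = "none",
    span: tuple[float, float] | None = None,
    seed: int = 0,
    _sub: int = 50,
) -> BranchingEstimate:
    """Branching-process inversion of progenitor/differentiated counts.

    Parameters
    ----------
    counts : CountsTimeSeries or (P, D) pair of callables
        The population curves.  A counts table can be used raw
        (``fit='none'``, linear interpolation between recorded points) or
        smoothed first (``fit='sigmoid'``).
    gamma, apoptosis_rate : callable or constant
        Growth fraction and progenitor death hazard (measured or true).
    grid : sequence of times
        Window edges; consecutive pairs form the estimation windows.
        Defaults to the counts' recorded span split into ~6 h windows.

    Per window [t0, t1]: ppdd = (ΔP+Φ)/(ΔP+ΔD+Φ), T = γ̄·I/(ΔP+ΔD+Φ);
    windows with non-positive division mass ΔP+ΔD+Φ are masked.
    """
    g = gamma if callable(gamma) else (lambda _t, _v=float(gamma): _v)
    phi = apoptosis_rate if callable(apoptosis_rate) else (lambda _t, _v=float(apoptosis_rate): _v)

    if isinstance(counts, CountsTimeSeries):
        fP, fD, t_lo, t_hi = _as_callables(counts, fit, seed)
    else:
        fP, fD = counts
        if span is None:
            raise InvalidParameterError("span=(t_lo, t_hi) is required with callable inputs")
        t_lo, t_hi = span

    if grid is None:
        n_win = max(1, int(round((t_hi - t_lo) / 6.0)))
        grid = np.linspace(t_lo, t_hi, n_win + 1)
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 2:
        raise InsufficientDataError("grid needs at least two edges")
    if grid[0] < t_lo - 1e-9 or grid[-1] > t_hi + 1e-9:
        raise InvalidParameterError("grid extends beyond the data span")

    k = len(grid) - 1
    mids = 0.5 * (grid[:-1] + grid[1:])
    ppdd_hat = np.full(k, np.nan)
    T_hat = np.full(k, np.nan)
    clipped = False
    for w in range(k):
        t0, t1 = grid[w], grid[w + 1]
        ts = np.linspace(t0, t1, _sub + 1)
        P = np.asarray(fP(ts), dtype=float)
        if np.any(P <= 0):
            continue  # progenitor pool extinct: estimates undefined
        dP = P[-1] - P[0]
        dD = float(fD(t1)) - float(fD(t0))
        I = float(np.trapezoid(P, ts))
        phis = np.array([phi(x) for x in ts])
        Phi = float(np.trapezoid(phis * P, ts))
        gammas = np.array([g(x) for x in ts])
        gbar = float(np.trapezoid(gammas, ts) / (t1 - t0))
        denom = dP + dD + Phi
        if denom <= 0:
            continue  # no net division mass in this window
        val = (dP + Phi) / denom
        if not -1.0 <= val <= 1.0:
            clipped = True
            val = float(np.clip(val, -1.0, 1.0))
        ppdd_hat[w] = val
        T_hat[w] = gbar * I / denom
    if clipped:
        warnings.warn("pp-dd estimate clipped into [-1, 1] in at least one window", stacklevel=2)
    return BranchingEstimate(mids, np.column_stack([grid[:-1], grid[1:]]), ppdd_hat, T_hat)


def propagate_ci50(
    times: Sequence[float],
    P: Sequence[float],
    P_se: Sequence[float],
    D: Sequence[float],
    D_se: Sequence[float],
    gamma: Callable[[float], float] | float = 1.0,
    apoptosis_rate: Callable[[float], float] | float = 0.0,
    grid: Sequence[float] | None = None,
    seed: int = 0,
) -> BranchingEstimate:
    """50% confidence bands for the branching-process estimate.

    Each count series is shifted by ± half of its maximum standard error,
    refitted with the three-parameter sigmoid, and the branching equations
    re-run on every (P-shift, D-shift) combination; the band is the
    envelope of those estimates around the unshifted point estimate.
    """
    times = np.asarray(times, dtype=float)
    P = np.asarray(P, dtype=float)
    D = np.asarray(D, dtype=float)
    hP = 0.5 * float(np.max(P_se))
    hD = 0.5 * float(np.max(D_se))
    span = (float(times[0]), float(times[-1]))

    def estimate(dp: float, dd: float) -> BranchingEstimate:
        fP = sigmoid_fit(times, np.clip(P + dp, 1e-9, None), seed=seed)
        fD = sigmoid_fit(times, np.clip(D + dd, 0.0, None), seed=seed + 1)
        return bp_estimate(
            (fP, fD), gamma, apoptosis_rate, grid=grid, span=span, seed=seed
        )

    center = estimate(0.0, 0.0)
    variants = [estimate(sp * hP, sd * hD) for sp in (-1.0, 1.0) for sd in (-1.0, 1.0)]
    pp_stack = np.vstack([v.ppdd_hat for v in variants] + [center.ppdd_hat])
    T_stack = np.vstack([v.T_hat for v in variants] + [center.T_hat])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        center.ppdd_lo = np.nanmin(pp_stack, axis=0)
        center.ppdd_hi = np.nanmax(pp_stack, axis=0)
        center.T_lo = np.nanmin(T_stack, axis=0)
        center.T_hi = np.nanmax(T_stack, axis=0)
    return center


def decompose_modes(ppdd: float) -> ModeRates:
    """Split the net self-renewal pp−dd into (pp, pd, dd) under independent
    daughter fates: p = (1+ppdd)/2, pp = p², pd = 2p(1−p), dd = (1−p)²."""
    if not -1.0 <= ppdd <= 1.0:
        raise InvalidParameterError(f"pp-dd must be in [-1, 1], got {ppdd}")
    p = (1.0 + ppdd) / 2.0
    return ModeRates(pp=p**2, pd=2 * p * (1 - p), dd=(1 - p) ** 2)
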