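"""Scenario library and harness comparing the four estimation methods.

Named scenarios re-create the benchmark conditions: a homeostatic
population with constant cycle length (the regime the cumulative-curve
method was designed for), a growing population, and conditions where the
cycle length and/or the mode of division vary over time.  Each scenario
is run as several independent simulations; every run is analysed with
all four methods (C1, C2, PC, BP) and the estimates are tabulated
against the scenario's true time-averaged cycle length.

The time-varying cycle-length profile is a smooth cosine
T(t) = 20 + 6·cos(2π t / t_end): exact time-average 20 h over the run,
range 14–26 h, dipping to 14 h mid-run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cellsim import (
    CountsTimeSeries,
    ScheduleSet,
    SimConfig,
    constant,
    run,
)
from .errors import CycleFateError, InvalidParameterError
from .estimators import BranchingEstimate, bp_estimate, c1_fit, c2_fit, pc_fit
from .labeling import (
    cumulative_experiment,
    dual_cumulative_experiment,
    pulse_chase_experiment,
)

__all__ = [
    "ScenarioSpec",
    "BenchmarkResult",
    "SCENARIO_NAMES",
    "make_scenario",
    "run_comparison",
    "forward_consistency",
    "factor_decomposition",
]

SCENARIO_NAMES = ("constant", "growing", "variable_T", "variable_mode", "variable_both")


def _cosine_T(mean: float, amplitude: float, period: float) -> Callable[[float], float]:
    def T(t: float) -> float:
        return mean + amplitude * math.cos(2 * math.pi * t / period)

    return T


def _ramp(v0: float, v1: float, t_end: float) -> Callable[[float], float]:
    def f(t: float) -> float:
        u = min(max(t / t_end, 0.0), 1.0)
        return v0 + (v1 - v0) * u

    return f


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully reproducible benchmark scenario."""

    name: str
    schedules: ScheduleSet
    m: int = 500
    t_end: float = 48.0
    n_runs: int = 10
    seed: int = 0
    dt: float = 0.1
    # protocol parameters
    fixation_grid: tuple[float, ...] = tuple(np.arange(2.0, 30.1, 2.0))
    c2_exposures: tuple[float, ...] = tuple(np.arange(2.0, 20.1, 2.0))
    c2_fixation: float = 30.0
    pc_grid: tuple[float, ...] = tuple(np.arange(2.0, 30.1, 2.0))
    pulse_width: float = 0.5
    bp_window_h: float = 6.0

    @property
    def true_T(self) -> float:
        """Time-average of T_mean over [0, t_end] (trapezoid, fine grid)."""
        ts = np.linspace(0.0, self.t_end, 2001)
        vals = np.array([self.schedules.T_mean(t) for t in ts])
        return float(np.trapezoid(vals, ts) / self.t_end)

    def sim_config(self, seed: int) -> SimConfig:
        return SimConfig(
            initial_count=self.m,
            t_end=self.t_end,
            dt=self.dt,
            seed=seed,
            schedules=self.schedules,
        )


def make_scenario(name: str, **overrides) -> ScenarioSpec:
    """Build a named scenario; keyword overrides replace any spec field or
    any schedule (T_mean, ppdd, gamma, apoptosis_rate, cv; constants or
    callables)."""
    if name not in SCENARIO_NAMES and name != "custom":
        raise InvalidParameterError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    t_end = float(overrides.pop("t_end", 48.0 if name in ("constant", "growing") else 30.0))
    sched_kwargs: dict = {}
    if name in ("constant", "growing"):
        sched_kwargs["T_mean"] = constant(20.0)
    else:  # variable_T / variable_mode / variable_both / custom
        if name in ("variable_T", "variable_both"):
            sched_kwargs["T_mean"] = _cosine_T(20.0, 6.0, t_end)
        else:
            sched_kwargs["T_mean"] = constant(20.0)
    if name == "growing":
        sched_kwargs["ppdd"] = constant(0.3)
    elif name in ("variable_mode", "variable_both"):
        sched_kwargs["ppdd"] = _ramp(0.5, -0.5, t_end)
    else:
        sched_kwargs["ppdd"] = constant(0.0)
    sched_kwargs["gamma"] = constant(1.0)
    sched_kwargs["apoptosis_rate"] = constant(0.0)
    for key in ("T_mean", "ppdd", "gamma", "apoptosis_rate", "cv"):
        if key in overrides:
            v = overrides.pop(key)
            sched_kwargs[key] = v if (callable(v) or key == "cv") else constant(float(v))
    schedules = ScheduleSet(**sched_kwargs)
    return ScenarioSpec(name=name, schedules=schedules, t_end=t_end, **overrides)


@dataclass
class BenchmarkResult:
    """Per-method estimates across runs, with failures flagged (NaN)."""

    scenario: ScenarioSpec
    estimates: dict[str, np.ndarray] = field(default_factory=dict)
    failures: dict[str, list[str]] = field(default_factory=dict)

    METHODS = ("C1", "C2", "PC", "BP")

    def summary(self) -> pd.DataFrame:
        true_T = self.scenario.true_T
        rows = []
        for method in self.METHODS:
            est = self.estimates[method]
            ok = est[np.isfinite(est)]
            mean = float(np.mean(ok)) if len(ok) else float("nan")
            sd = float(np.std(ok, ddof=1)) if len(ok) > 1 else float("nan")
            rows.append(
                {
                    "method": method,
                    "n_runs": len(est),
                    "n_failed": int(np.sum(~np.isfinite(est))),
                    "mean_T": mean,
                    "sd_T": sd,
                    "rel_err_of_mean": abs(mean - true_T) / true_T,
                    "mean_abs_rel_err": float(np.mean(np.abs(ok - true_T) / true_T))
                    if len(ok)
                    else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        true_T = self.scenario.true_T
        recs = []
        for method, est in self.estimates.items():
            for r, v in enumerate(est):
                recs.append(
                    {
                        "method": method,
                        "run": r,
                        "estimate_h": v,
                        "rel_err": abs(v - true_T) / true_T if np.isfinite(v) else float("nan"),
                    }
                )
        return pd.DataFrame(recs)


def run_comparison(scenario: ScenarioSpec, methods: Sequence[str] = ("C1", "C2", "PC", "BP")) -> BenchmarkResult:
    """Run the scenario ``n_runs`` times and estimate T with each method.

    Each run owns an independent seed; within a run, each labeling arm
    (single cumulative, dual cumulative, pulse-chase) and the unlabeled
    counts arm are separate simulated experiments, exactly as separate
    dishes would be in the laboratory.
    """
    children = np.random.SeedSequence(scenario.seed).spawn(scenario.n_runs)
    result = BenchmarkResult(scenario, {m: np.full(scenario.n_runs, np.nan) for m in methods},
                             {m: [] for m in methods})
    sched = scenario.schedules
    for r, child in enumerate(children):
        arm_seeds = np.random.default_rng(child).integers(2**31, size=4)
        if "C1" in methods:
            try:
                curve = cumulative_experiment(
                    scenario.sim_config(int(arm_seeds[0])), 0.0, scenario.fixation_grid
                )
                result.estimates["C1"][r] = c1_fit(curve).T_hat
            except CycleFateError as exc:
                result.failures["C1"].append(f"run {r}: {exc}")
        if "C2" in methods:
            try:
                starts = tuple(scenario.c2_fixation - d for d in scenario.c2_exposures)
                curve = dual_cumulative_experiment(
                    scenario.sim_config(int(arm_seeds[1])), 0.0, starts, scenario.c2_fixation
                )
                result.estimates["C2"][r] = c2_fit(curve).T_hat
            except CycleFateError as exc:
                result.failures["C2"].append(f"run {r}: {exc}")
        if "PC" in methods:
            try:
                curve = pulse_chase_experiment(
                    scenario.sim_config(int(arm_seeds[2])),
                    0.0,
                    scenario.pulse_width,
                    scenario.pc_grid,
                )
                result.estimates["PC"][r] = pc_fit(curve).T_hat
            except CycleFateError as exc:
                result.failures["PC"].append(f"run {r}: {exc}")
        if "BP" in methods:
            try:
                counts = run(scenario.sim_config(int(arm_seeds[3])))
                n_win = max(1, int(round(scenario.t_end / scenario.bp_window_h)))
                grid = np.linspace(0.0, scenario.t_end, n_win + 1)
                est = bp_estimate(
                    counts, sched.gamma, sched.apoptosis_rate, grid=grid, fit="none"
                )
                result.estimates["BP"][r] = est.mean_T()
            except CycleFateError as exc:
                result.failures["BP"].append(f"run {r}: {exc}")
    return result


def schedules_from_estimate(
    estimate: BranchingEstimate,
    gamma: Callable[[float], float] | float = 1.0,
    apoptosis_rate: Callable[[float], float] | float = 0.0,
    cv: float = 0.30,
) -> ScheduleSet:
    """Turn a time-resolved branching-process estimate into forward-model
    schedules (linear interpolation between window midpoints, NaN windows
    dropped)."""
    ok = np.isfinite(estimate.T_hat) & np.isfinite(estimate.ppdd_hat)
    if not np.any(ok):
        raise CycleFateError("estimate has no defined windows")
    ts = estimate.grid[ok]
    Ts = estimate.T_hat[ok]
    pps = estimate.ppdd_hat[ok]
    g = gamma if callable(gamma) else constant(float(gamma))
    a = apoptosis_rate if callable(apoptosis_rate) else constant(float(apoptosis_rate))
    return ScheduleSet(
        T_mean=lambda t: float(np.interp(t, ts, Ts)),
        ppdd=lambda t: float(np.interp(t, ts, pps)),
        gamma=g,
        apoptosis_rate=a,
        cv=cv,
    )


def forward_consistency(
    counts: CountsTimeSeries,
    estimate: BranchingEstimate,
    gamma: Callable[[float], float] | float = 1.0,
    apoptosis_rate: Callable[[float], float] | float = 0.0,
    n_sims: int = 30,
    seed: int = 0,
    dt: float = 0.1,
) -> dict:
    """Forward-simulate the estimated schedules and report how many of the
    observed count points fall inside the simulated 5–95% envelope.

    This closes the loop: if populations simulated with the estimated
    T(t) and pp−dd(t) reproduce the observed P(t) and D(t), the estimates
    are self-consistent.
    """
    if len(counts) == 0:
        return {"coverage_P": float("nan"), "coverage_D": float("nan"), "n_points": 0}
    sched = schedules_from_estimate(estimate, gamma, apoptosis_rate)
    t = counts.time
    t_span = float(t[-1] - t[0])
    m0 = int(round(counts.column("P")[0]))
    children = np.random.SeedSequence(seed).spawn(n_sims)
    P_sims = np.empty((n_sims, len(t)))
    D_sims = np.empty((n_sims, len(t)))
    D0 = counts.column("D")[0]
    rec = float(np.min(np.diff(t))) if len(t) > 1 else 1.0
    for i, child in enumerate(children):
        cfg = SimConfig(
            initial_count=m0,
            t_end=t_span,
            dt=dt,
            seed=0,
            schedules=sched,
            record_interval=min(rec, t_span),
        )
        sim = run(cfg, rng=np.random.default_rng(child))
        P_sims[i] = np.interp(t - t[0], sim.time, sim.column("P"))
        D_sims[i] = D0 + np.interp(t - t[0], sim.time, sim.column("D"))
    lo_P, hi_P = np.percentile(P_sims, [5, 95], axis=0)
    lo_D, hi_D = np.percentile(D_sims, [5, 95], axis=0)
    P_obs = counts.column("P")
    D_obs = counts.column("D")
    return {
        "coverage_P": float(np.mean((P_obs >= lo_P) & (P_obs <= hi_P))),
        "coverage_D": float(np.mean((D_obs >= lo_D) & (D_obs <= hi_D))),
        "n_points": len(t),
        "envelope_P": (lo_P, hi_P),
        "envelope_D": (lo_D, hi_D),
    }


_FACTORS = ("T", "gamma", "ppdd")


def factor_decomposition(
    baseline: ScheduleSet,
    alternative: ScheduleSet,
    horizon: float = 22.0,
    factors: Sequence[Sequence[str]] | None = None,
    n_sims: int = 30,
    m: int = 500,
    seed: int = 0,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Counterfactual decomposition: substitute selected schedule factors
    from ``alternative`` into ``baseline`` and report the mean % change in
    cycling progenitors at the horizon relative to all-baseline.
    """
    if factors is None:
        factors = [("T",), ("gamma",), ("ppdd",), ("T", "ppdd"), ("T", "gamma", "ppdd")]
    for sub in factors:
        for f in sub:
            if f not in _FACTORS:
                raise InvalidParameterError(f"unknown factor {f!r}; choose from {_FACTORS}")

    def hybrid(subset) -> ScheduleSet:
        kwargs = {
            "T_mean": alternative.T_mean if "T" in subset else baseline.T_mean,
            "gamma": alternative.gamma if "gamma" in subset else baseline.gamma,
            "ppdd": alternative.ppdd if "ppdd" in subset else baseline.ppdd,
            "apoptosis_rate": baseline.apoptosis_rate,
            "cv": baseline.cv,
        }
        return ScheduleSet(**kwargs)

    def mean_cycling(sched: ScheduleSet, ss: np.random.SeedSequence) -> tuple[float, float]:
        vals = np.empty(n_sims)
        for i, child in enumerate(ss.spawn(n_sims)):
            cfg = SimConfig(
                initial_count=m, t_end=horizon, dt=dt, seed=0,
                schedules=sched, record_interval=horizon,
            )
            sim = run(cfg, rng=np.random.default_rng(child))
            vals[i] = sim.column("P_cycling")[-1]
        return float(np.mean(vals)), float(np.std(vals, ddof=1) / np.sqrt(n_sims))

    root = np.random.SeedSequence(seed).spawn(len(factors) + 1)
    base_mean, base_se = mean_cycling(baseline, root[0])
    rows = []
    for sub, ss in zip(factors, root[1:]):
        alt_mean, alt_se = mean_cycling(hybrid(sub), ss)
        pct = 100.0 * (alt_mean - base_mean) / base_mean
        pct_se = 100.0 * np.hypot(alt_se, base_se * alt_mean / base_mean) / base_mean
        rows.append(
            {
                "factors": "+".join(sub),
                "mean_P_cycling": alt_mean,
                "baseline_P_cycling": base_mean,
                "pct_change": pct,
                "pct_change_se": float(pct_se),
            }
        )
    return pd.DataFrame(rows)
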