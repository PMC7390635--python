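"""In-silico thymidine-analog (EdU/BrdU-like) labeling layer.

Cells in S phase while a label window is active become permanently
positive for that label; both daughters inherit every label at division
(binary DNA label, no dilution).  The three experiment drivers below
emulate the classical designs:

* cumulative: one analog added at a fixed time, identical samples fixed at
  increasing exposure durations (labeled fraction rises with slope
  ~ gamma/T, then plateaus at gamma);
* dual cumulative: a first analog shared by all samples plus a second
  analog added at staggered times, all fixed together;
* pulse-chase: a short pulse marks the S-phase cohort, whose re-entry
  into a later S phase (detected with a second short pulse or an
  instantaneous S gate) peaks one cycle after the pulse.

Each fixation time is an independent simulated replicate ("several
identical samples"), seeded from a spawned child of the master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cellsim import Population, SimConfig, run
from .errors import InsufficientDataError, InvalidProtocolError

__all__ = [
    "LabelProtocol",
    "CumulativeCurve",
    "apply_labeling",
    "labeled_progenitor_fraction",
    "cumulative_experiment",
    "dual_cumulative_experiment",
    "pulse_chase_experiment",
]


@dataclass(frozen=True)
class LabelProtocol:
    """One labeling agent and its exposure windows."""

    label_name: str
    windows: tuple[tuple[float, float], ...]
    kind: str = "cumulative"  # cumulative | pulse | dual_second

    def __post_init__(self) -> None:
        ws = sorted(self.windows)
        for start, end in ws:
            if not start < end:
                raise InvalidProtocolError(f"window start {start} must be < end {end}")
        for (_, e0), (s1, _) in zip(ws, ws[1:]):
            if s1 < e0:
                raise InvalidProtocolError("label windows must not overlap")

    def active(self, t0: float, t1: float) -> bool:
        """Is any window active during (t0, t1]?"""
        return any(s < t1 and e > t0 for s, e in self.windows)


@dataclass
class CumulativeCurve:
    """Labeled-progenitor fraction versus exposure duration."""

    exposure_h: np.ndarray
    fraction: np.ndarray
    se: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.exposure_h = np.asarray(self.exposure_h, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise InvalidProtocolError("fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.exposure_h)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure_h": self.exposure_h,
                "fraction": self.fraction,
                "se": self.se,
                "n": self.n,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CumulativeCurve":
        f = pd.read_csv(path)
        return cls(f["exposure_h"], f["fraction"], f["se"], f["n"])


def apply_labeling(
    population: Population,
    t: float,
    dt: float,
    protocols,
    phase_fractions=(1 / 3, 1 / 3, 1 / 3),
) -> Population:
    """Mark cycling cells that traversed S phase during (t, t+dt] while a
    window was active.

    Called after aging, so a cycling cell's age interval over the step is
    [age - dt, age).  The cell is labeled if that interval intersects its
    own S interval [g1*T, (g1+s)*T).  Quiescent and differentiated cells
    never acquire labels.
    """
    g1, s, _ = phase_fractions
    cyc = population.is_cycling
    if not np.any(cyc):
        return population
    lo = population.age - dt
    hi = population.age
    s_lo = g1 * population.cycle_length
    s_hi = (g1 + s) * population.cycle_length
    in_s = cyc & (hi > s_lo) & (lo < s_hi)
    for b, proto in enumerate(protocols):
        if proto.active(t, t + dt):
            population.labels[in_s] |= np.uint32(1 << b)
    return population


def labeled_progenitor_fraction(counts_row: pd.Series, gate: str) -> tuple[float, float, int]:
    """(fraction, binomial SE, n) of label-positive progenitors in one row."""
    n = int(counts_row["P"])
    if n == 0:
        return 0.0, 0.0, 0
    f = float(counts_row[gate]) / n
    se = float(np.sqrt(f * (1 - f) / n))
    return f, se, n


def _replicate_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master_seed).spawn(n)


def cumulative_experiment(
    config: SimConfig,
    label_start: float,
    fixation_times,
) -> CumulativeCurve:
    """Single cumulative-curve design: one label added at ``label_start``,
    one independent replicate fixed at each of ``fixation_times``.

    Returns labeled-progenitor fraction (denominator: cycling + quiescent
    progenitors) against exposure duration = fixation - label_start.
    """
    fixation_times = sorted(float(t) for t in fixation_times)
    if len(fixation_times) == 0:
        return CumulativeCurve(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
    if min(fixation_times) <= label_start:
        raise InvalidProtocolError("all fixation times must come after label_start")
    seeds = _replicate_seeds(config.seed, len(fixation_times))
    exposure, frac, se, npts = [], [], [], []
    for fix, ss in zip(fixation_times, seeds):
        proto = LabelProtocol("edu", ((label_start, fix),), kind="cumulative")
        cfg = config.with_(t_end=fix, protocols=(proto,))
        counts = run(cfg, rng=np.random.default_rng(ss))
        f, s, n = labeled_progenitor_fraction(counts.frame.iloc[-1], "P_edu")
        exposure.append(fix - label_start)
        frac.append(f)
        se.append(s)
        npts.append(n)
    return CumulativeCurve(np.array(exposure), np.array(frac), np.array(se), np.array(npts))


def dual_cumulative_experiment(
    config: SimConfig,
    first_label_start: float,
    second_label_starts,
    common_fixation: float,
) -> CumulativeCurve:
    """Dual cumulative design: shared first label, staggered second label,
    common fixation.

    Returns the double-positive progenitor fraction against the second
    label's exposure duration (common_fixation - second_start), ascending.
    """
    starts = sorted(float(t) for t in second_label_starts)
    if len(starts) == 0:
        return CumulativeCurve(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
    if not first_label_start < min(starts):
        raise InvalidProtocolError("first label must start before every second label")
    if max(starts) >= common_fixation:
        raise InvalidProtocolError("second labels must start before the common fixation")
    seeds = _replicate_seeds(config.seed, len(starts))
    exposure, frac, se, npts = [], [], [], []
    for s2, ss in zip(starts, seeds):
        protoA = LabelProtocol("eduA", ((first_label_start, common_fixation),))
        protoB = LabelProtocol("eduB", ((s2, common_fixation),), kind="dual_second")
        cfg = config.with_(t_end=common_fixation, protocols=(protoA, protoB))
        f, s_, n = _double_positive_fraction(cfg, ss)
        exposure.append(common_fixation - s2)
        frac.append(f)
        se.append(s_)
        npts.append(n)
    order = np.argsort(exposure)
    return CumulativeCurve(
        np.array(exposure)[order], np.array(frac)[order], np.array(se)[order], np.array(npts)[order]
    )


def _double_positive_fraction(cfg: SimConfig, seed_seq) -> tuple[float, float, int]:
    """Run ``cfg`` to t_end and report the fraction of progenitors positive
    for both of its (exactly two) protocols."""
    from .cellsim import init_population, step

    rng = np.random.default_rng(seed_seq)
    pop = init_population(cfg, rng)
    n_steps = int(round(cfg.t_end / cfg.dt))
    for k in range(n_steps):
        step(
            pop,
            k * cfg.dt,
            cfg.dt,
            cfg.schedules,
            rng,
            protocols=cfg.protocols,
            phase_fractions=cfg.phase_fractions,
            mode_triplet=cfg.mode_triplet,
        )
    prog = pop.is_progenitor
    n = int(prog.sum())
    if n == 0:
        return 0.0, 0.0, 0
    both = prog & (pop.labels & 1).astype(bool) & (pop.labels >> 1 & 1).astype(bool)
    f = int(both.sum()) / n
    return f, float(np.sqrt(f * (1 - f) / n)), n


def pulse_chase_experiment(
    config: SimConfig,
    pulse_at: float,
    pulse_width: float,
    chase_times,
    detector: str = "second_pulse",
    detector_width: float = 0.5,
) -> CumulativeCurve:
    """Pulse-chase design: a short pulse marks the S-phase cohort; each
    chase time is an independent replicate fixed at pulse_at + chase.

    ``detector`` is either a second short analog pulse immediately before
    fixation (``second_pulse``) or an instantaneous gate on cells currently
    in S (``mitosis_gate`` analog: cells re-entering S).  Returns the
    double-positive progenitor fraction versus chase time (measured from
    the start of the pulse).
    """
    T0 = config.schedules.T_mean(pulse_at)
    if pulse_width > T0 / 10:
        warnings.warn(
            f"pulse width {pulse_width} h is long relative to T ({T0} h); "
            "the labeled cohort will not be a clean S-phase snapshot",
            stacklevel=2,
        )
    chase_times = sorted(float(c) for c in chase_times)
    if len(chase_times) == 0:
        raise InsufficientDataError("need at least one chase time")
    if min(chase_times) <= pulse_width:
        raise InvalidProtocolError("chase times must exceed the pulse width")
    if max(chase_times) < 1.5 * T0:
        warnings.warn(
            "chase window shorter than ~1.5 cycles; the re-entry peak may not be bracketed",
            stacklevel=2,
        )
    seeds = _replicate_seeds(config.seed, len(chase_times))
    exposure, frac, se, npts = [], [], [], []
    for chase, ss in zip(chase_times, seeds):
        fix = pulse_at + chase
        protoA = LabelProtocol("pulse", ((pulse_at, pulse_at + pulse_width),), kind="pulse")
        if detector == "second_pulse":
            protoB = LabelProtocol(
                "detect", ((max(pulse_at + pulse_width, fix - detector_width), fix),), kind="pulse"
            )
            cfg = config.with_(t_end=fix, protocols=(protoA, protoB))
            f, s_, n = _double_positive_fraction(cfg, ss)
        elif detector == "mitosis_gate":
            f, s_, n = _pulse_then_s_gate(config, protoA, fix, ss)
        else:
            raise InvalidProtocolError(f"unknown detector {detector!r}")
        exposure.append(chase)
        frac.append(f)
        se.append(s_)
        npts.append(n)
    return CumulativeCurve(np.array(exposure), np.array(frac), np.array(se), np.array(npts))


def _pulse_then_s_gate(config, protoA, fix, seed_seq) -> tuple[float, float, int]:
    """Fraction of progenitors pulse-positive AND currently in S at fixation."""
    from .cellsim import init_population, step

    cfg = config.with_(t_end=fix, protocols=(protoA,))
    rng = np.random.default_rng(seed_seq)
    pop = init_population(cfg, rng)
    n_steps = int(round(cfg.t_end / cfg.dt))
    for k in range(n_steps):
        step(
            pop,
            k * cfg.dt,
            cfg.dt,
            cfg.schedules,
            rng,
            protocols=cfg.protocols,
            phase_fractions=cfg.phase_fractions,
            mode_triplet=cfg.mode_triplet,
        )
    g1, s, _ = cfg.phase_fractions
    prog = pop.is_progenitor
    n = int(prog.sum())
    if n == 0:
        return 0.0, 0.0, 0
    in_s = (
        pop.is_cycling
        & (pop.age >= g1 * pop.cycle_length)
        & (pop.age < (g1 + s) * pop.cycle_length)
    )
    both = prog & in_s & (pop.labels & 1).astype(bool)
    f = int(both.sum()) / n
    return f, float(np.sqrt(f * (1 - f) / n)), n
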