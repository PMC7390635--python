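"""Agent-based simulator of a differentiating progenitor population.

The population model tracks individual cells, each carrying its own cycle
length (drawn from a gamma distribution around a possibly time-varying
mean), its age, its phase (G1 / S / G2M as thirds of the cycle by default),
its state (cycling, quiescent, differentiated) and a heritable set of
thymidine-analog labels.  Cycling cells age, divide when their age reaches
their cycle length, and each daughter independently keeps the progenitor
identity with probability (1 + ppdd)/2 or differentiates terminally.
Quiescence is modelled as a reversible exit from the cycle whose occupancy
tracks the growth-fraction schedule gamma(t); apoptosis is a continuous
per-hour hazard acting on all progenitors.

For performance the live population is stored as a structure of numpy
arrays; :class:`CellRecord` offers a per-cell view for inspection and small
oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidParameterError

__all__ = [
    "STATE_CYCLING",
    "STATE_QUIESCENT",
    "STATE_DIFFERENTIATED",
    "CellRecord",
    "ScheduleSet",
    "SimConfig",
    "CountsTimeSeries",
    "Population",
    "constant",
    "piecewise_linear",
    "draw_cycle_length",
    "init_population",
    "divide",
    "step",
    "run",
]

STATE_CYCLING = 0
STATE_QUIESCENT = 1
STATE_DIFFERENTIATED = 2

_RNG_ALGORITHM = "PCG64"


def constant(value: float) -> Callable[[float], float]:
    """A constant schedule: ``constant(20.0)(t) == 20.0`` for every t."""

    def f(_t: float) -> float:
        return value

    f.__name__ = f"constant_{value}"
    return f


def piecewise_linear(breakpoints: Sequence[tuple[float, float]]) -> Callable[[float], float]:
    """Linear interpolation through ``(t, value)`` breakpoints, clamped at the ends."""
    pts = sorted(breakpoints)
    ts = np.array([p[0] for p in pts], dtype=float)
    vs = np.array([p[1] for p in pts], dtype=float)

    def f(t: float) -> float:
        return float(np.interp(t, ts, vs))

    return f


@dataclass(frozen=True)
class CellRecord:
    """A single simulated cell.

    ``phase`` is derived from ``age`` and the per-cell ``cycle_length``:
    G1 while age < T/3, S while T/3 <= age < 2T/3, G2M afterwards
    (equal thirds by default; the boundaries move with ``phase_fractions``
    of the owning config).  ``labels`` is a set of (name, acquisition time)
    pairs and only ever grows.
    """

    id: int
    birth_time: float
    cycle_length: float
    age: float
    phase: str
    state: str
    labels: frozenset = frozenset()


@dataclass(frozen=True)
class ScheduleSet:
    """Time-dependent input parameters of the population model.

    Parameters
    ----------
    T_mean : callable
        Mean cycle length (hours) at time t.
    ppdd : callable
        Net self-renewal per division, pp - dd, in [-1, 1].
    gamma : callable
        Growth fraction (fraction of progenitors cycling), in [0, 1].
    apoptosis_rate : callable
        Per-progenitor hazard of death, per hour, >= 0.
    cv : float
        Coefficient of variation of the per-cell cycle-length draw.
    """

    T_mean: Callable[[float], float] = constant(20.0)
    ppdd: Callable[[float], float] = constant(0.0)
    gamma: Callable[[float], float] = constant(1.0)
    apoptosis_rate: Callable[[float], float] = constant(0.0)
    cv: float = 0.30

    def validate_at(self, t: float) -> None:
        if self.T_mean(t) <= 0:
            raise InvalidConfigError(f"T_mean({t}) = {self.T_mean(t)} must be > 0")
        if not -1.0 <= self.ppdd(t) <= 1.0:
            raise InvalidConfigError(f"ppdd({t}) = {self.ppdd(t)} outside [-1, 1]")
        if not 0.0 <= self.gamma(t) <= 1.0:
            raise InvalidConfigError(f"gamma({t}) = {self.gamma(t)} outside [0, 1]")
        if self.apoptosis_rate(t) < 0:
            raise InvalidConfigError(f"apoptosis_rate({t}) < 0")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulation run."""

    initial_count: int = 500
    t_end: float = 48.0
    dt: float = 0.1
    seed: int = 0
    schedules: ScheduleSet = field(default_factory=ScheduleSet)
    protocols: tuple = ()  # LabelProtocol instances (see labeling module)
    record_interval: float = 1.0
    # (G1, S, G2M) fractions of the cycle; equal thirds unless overridden.
    phase_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    # If set, daughter fates are drawn as whole-division modes from this
    # (pp, pd, dd) triplet instead of independently per daughter.
    mode_triplet: tuple[float, float, float] | None = None

    def validate(self) -> None:
        if self.initial_count < 0:
            raise InvalidConfigError("initial_count must be >= 0")
        if not (0 < self.dt <= self.record_interval <= self.t_end):
            raise InvalidConfigError(
                "need 0 < dt <= record_interval <= t_end "
                f"(got dt={self.dt}, record_interval={self.record_interval}, t_end={self.t_end})"
            )
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise InvalidConfigError("phase_fractions must sum to 1")
        if self.mode_triplet is not None:
            pp, pd_, dd = self.mode_triplet
            if min(pp, pd_, dd) < 0 or abs(pp + pd_ + dd - 1.0) > 1e-9:
                raise InvalidConfigError("mode_triplet must be a probability triplet")
        self.schedules.validate_at(0.0)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class CountsTimeSeries:
    """Per-time counts of the population, the universal exchange table.

    Columns: ``time_h``, ``P`` (all progenitors = cycling + quiescent),
    ``P_cycling``, ``D`` (terminally differentiated), ``Q`` (quiescent),
    ``A`` (cumulative apoptotic) and one ``P_<label>`` column per label
    gate counting label-positive progenitors.
    """

    frame: pd.DataFrame
    rng_algorithm: str = _RNG_ALGORITHM

    REQUIRED = ("time_h", "P", "D")

    def __post_init__(self) -> None:
        from .errors import SchemaError

        f = self.frame
        missing = [c for c in self.REQUIRED if c not in f.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        t = f["time_h"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise SchemaError("time_h must be strictly increasing")
        num = f.select_dtypes("number")
        if (num.to_numpy() < 0).any():
            bad = f.index[(num < 0).any(axis=1)].tolist()
            raise SchemaError(f"negative counts in rows {bad}")

    @property
    def time(self) -> np.ndarray:
        return self.frame["time_h"].to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    @property
    def label_columns(self) -> list[str]:
        skip = {"time_h", "P", "P_cycling", "D", "Q", "A"}
        return [c for c in self.frame.columns if c not in skip]

    def __len__(self) -> int:
        return len(self.frame)


def draw_cycle_length(mean: float, cv: float, rng: np.random.Generator, size: int | None = None):
    """Draw per-cell cycle lengths.

    Gamma distributed with the requested mean and standard deviation
    ``cv * mean`` (shape 1/cv^2, scale mean*cv^2); ``cv = 0`` collapses to
    the mean exactly.
    """
    if mean <= 0:
        raise InvalidParameterError(f"cycle-length mean must be > 0, got {mean}")
    if not 0 <= cv < 1:
        raise InvalidParameterError(f"cv must be in [0, 1), got {cv}")
    if cv == 0:
        return mean if size is None else np.full(size, mean)
    shape = 1.0 / cv**2
    scale = mean * cv**2
    return rng.gamma(shape, scale, size=size)


class Population:
    """Structure-of-arrays container for the live population.

    Differentiated cells are kept in the arrays (their label sets matter
    for none of the current outputs but their counts do); apoptotic cells
    are removed and only counted cumulatively.
    """

    def __init__(self, state, cycle_length, age, birth_time, labels) -> None:
        self.state = np.asarray(state, dtype=np.int8)
        self.cycle_length = np.asarray(cycle_length, dtype=float)
        self.age = np.asarray(age, dtype=float)
        self.birth_time = np.asarray(birth_time, dtype=float)
        self.labels = np.asarray(labels, dtype=np.uint32)  # bitmask per cell
        # bookkeeping for conservation checks
        self.apoptotic = 0
        self.divisions = 0
        self.created = len(self.state)

    def __len__(self) -> int:
        return len(self.state)

    # -- views -----------------------------------------------------------
    def phase_of(self, i: int, phase_fractions=(1 / 3, 1 / 3, 1 / 3)) -> str:
        g1, s, _ = phase_fractions
        frac = self.age[i] / self.cycle_length[i]
        if frac < g1:
            return "G1"
        if frac < g1 + s:
            return "S"
        return "G2M"

    def to_records(self, label_names: Sequence[str] = ()) -> list[CellRecord]:
        state_names = {0: "cycling", 1: "quiescent", 2: "differentiated"}
        out = []
        for i in range(len(self)):
            labs = frozenset(
                (name, float("nan"))
                for b, name in enumerate(label_names)
                if self.labels[i] >> b & 1
            )
            out.append(
                CellRecord(
                    id=i,
                    birth_time=float(self.birth_time[i]),
                    cycle_length=float(self.cycle_length[i]),
                    age=float(self.age[i]),
                    phase=self.phase_of(i),
                    state=state_names[int(self.state[i])],
                    labels=labs,
                )
            )
        return out

    # -- masks -----------------------------------------------------------
    @property
    def is_progenitor(self) -> np.ndarray:
        return self.state != STATE_DIFFERENTIATED

    @property
    def is_cycling(self) -> np.ndarray:
        return self.state == STATE_CYCLING

    def counts_row(self, t: float, n_labels: int = 0) -> dict:
        prog = self.is_progenitor
        cyc = self.is_cycling
        row = {
            "time_h": t,
            "P": int(prog.sum()),
            "P_cycling": int(cyc.sum()),
            "D": int((self.state == STATE_DIFFERENTIATED).sum()),
            "Q": int((self.state == STATE_QUIESCENT).sum()),
            "A": int(self.apoptotic),
        }
        for b in range(n_labels):
            row[f"_label{b}"] = int((prog & (self.labels >> b & 1).astype(bool)).sum())
        return row

    def keep(self, mask: np.ndarray) -> None:
        self.state = self.state[mask]
        self.cycle_length = self.cycle_length[mask]
        self.age = self.age[mask]
        self.birth_time = self.birth_time[mask]
        self.labels = self.labels[mask]

    def append(self, state, cycle_length, age, birth_time, labels) -> None:
        self.state = np.concatenate([self.state, np.asarray(state, dtype=np.int8)])
        self.cycle_length = np.concatenate([self.cycle_length, cycle_length])
        self.age = np.concatenate([self.age, age])
        self.birth_time = np.concatenate([self.birth_time, birth_time])
        self.labels = np.concatenate([self.labels, np.asarray(labels, dtype=np.uint32)])


def init_population(config: SimConfig, rng: np.random.Generator | None = None) -> Population:
    """Create the unsynchronized initial population at t = 0.

    Each of the ``initial_count`` cells draws its own cycle length, an age
    uniform on [0, cycle_length) and is quiescent with probability
    1 - gamma(0), cycling otherwise.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.initial_count
    sched = config.schedules
    L = np.atleast_1d(draw_cycle_length(sched.T_mean(0.0), sched.cv, rng, size=m)).astype(float)
    age = rng.uniform(0.0, L) if m else np.empty(0)
    g0 = sched.gamma(0.0)
    quiescent = rng.random(m) >= g0
    state = np.where(quiescent, STATE_QUIESCENT, STATE_CYCLING).astype(np.int8)
    pop = Population(state, L, age, np.zeros(m), np.zeros(m, dtype=np.uint32))
    return pop


def divide(
    cell: CellRecord,
    ppdd_now: float,
    rng: np.random.Generator,
    T_mean_now: float,
    cv: float = 0.30,
    division_time: float = 0.0,
) -> tuple[CellRecord, CellRecord]:
    """Per-division semantics on a single cell record.

    Each daughter independently remains a progenitor with probability
    p = (1 + ppdd)/2, otherwise terminally differentiates; both inherit the
    mother's labels and start at age 0 with fresh cycle-length draws.
    """
    if not -1.0 <= ppdd_now <= 1.0:
        raise InvalidParameterError(f"ppdd must be in [-1, 1], got {ppdd_now}")
    if cell.state != "cycling" or cell.age < cell.cycle_length:
        raise InvalidParameterError("only a cycling cell at the end of its cycle divides")
    p = (1.0 + ppdd_now) / 2.0
    daughters = []
    for k in (0, 1):
        progenitor = rng.random() < p
        daughters.append(
            CellRecord(
                id=2 * cell.id + k,
                birth_time=division_time,
                cycle_length=float(draw_cycle_length(T_mean_now, cv, rng)),
                age=0.0,
                phase="G1",
                state="cycling" if progenitor else "differentiated",
                labels=cell.labels,
            )
        )
    return daughters[0], daughters[1]


def _daughter_fates(n_div: int, ppdd_now: float, rng, mode_triplet=None) -> np.ndarray:
    """Boolean (2*n_div,) array, True where the daughter stays a progenitor.

    Independent per-daughter fates by default; with a (pp, pd, dd) triplet
    the whole-division mode is drawn instead.
    """
    if mode_triplet is None:
        p = (1.0 + ppdd_now) / 2.0
        return rng.random(2 * n_div) < p
    pp, pd_, dd = mode_triplet
    modes = rng.choice(3, size=n_div, p=[pp, pd_, dd])
    fates = np.empty((n_div, 2), dtype=bool)
    fates[modes == 0] = (True, True)
    fates[modes == 2] = (False, False)
    asym = modes == 1
    # asymmetric: randomize which daughter keeps the progenitor identity
    first = rng.random(int(asym.sum())) < 0.5
    fates[asym, 0] = first
    fates[asym, 1] = ~first
    return fates.ravel()


def step(
    population: Population,
    t: float,
    dt: float,
    schedules: ScheduleSet,
    rng: np.random.Generator,
    protocols: Sequence = (),
    phase_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    mode_triplet=None,
) -> Population:
    """Advance the population from t to t + dt (in place; returned for chaining).

    Order of sub-events inside a step: apoptosis hazard, aging, labeling,
    division, quiescence tracking.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    pop = population
    if len(pop) == 0:
        return pop

    # 1) apoptosis: continuous hazard on all progenitors
    rate = schedules.apoptosis_rate(t)
    if rate > 0:
        prog = pop.is_progenitor
        die = prog & (rng.random(len(pop)) < -np.expm1(-rate * dt))
        n_dead = int(die.sum())
        if n_dead:
            pop.apoptotic += n_dead
            pop.keep(~die)
            if len(pop) == 0:
                return pop

    # 2) aging of cycling cells
    cyc = pop.is_cycling
    pop.age[cyc] += dt

    # 3) labeling (cells whose age interval overlapped their S window
    #    while a protocol window was active)
    if protocols:
        from .labeling import apply_labeling

        apply_labeling(pop, t, dt, protocols, phase_fractions=phase_fractions)

    # 4) divisions
    div = pop.is_cycling & (pop.age >= pop.cycle_length)
    n_div = int(div.sum())
    if n_div:
        t_div = t + dt
        fates = _daughter_fates(n_div, schedules.ppdd(t), rng, mode_triplet)
        L_new = np.atleast_1d(
            draw_cycle_length(schedules.T_mean(t_div), schedules.cv, rng, size=2 * n_div)
        ).astype(float)
        labels_new = np.repeat(pop.labels[div], 2)
        state_new = np.where(fates, STATE_CYCLING, STATE_DIFFERENTIATED).astype(np.int8)
        pop.keep(~div)
        pop.append(
            state_new,
            L_new,
            np.zeros(2 * n_div),
            np.full(2 * n_div, t_div),
            labels_new,
        )
        pop.divisions += n_div
        pop.created += 2 * n_div

    # 5) quiescence occupancy tracking toward gamma(t+dt)
    _track_quiescence(pop, t + dt, schedules, rng)
    return pop


def _track_quiescence(pop: Population, t: float, schedules: ScheduleSet, rng) -> None:
    """Move randomly chosen cells between cycling and quiescent so that the
    cycling fraction of progenitors tracks gamma(t).

    Re-activated cells restart at age 0 with a fresh cycle-length draw
    (re-entry through G1).  Under constant schedules the net flux is at the
    rounding level, so label leakage into the quiescent pool is negligible.
    """
    g = schedules.gamma(t)
    prog_idx = np.flatnonzero(pop.is_progenitor)
    n_prog = len(prog_idx)
    if n_prog == 0:
        return
    cyc_idx = prog_idx[pop.state[prog_idx] == STATE_CYCLING]
    target = int(round(g * n_prog))
    n_cyc = len(cyc_idx)
    if n_cyc > target:
        chosen = rng.choice(cyc_idx, size=n_cyc - target, replace=False)
        pop.state[chosen] = STATE_QUIESCENT
    elif n_cyc < target:
        q_idx = prog_idx[pop.state[prog_idx] == STATE_QUIESCENT]
        k = min(target - n_cyc, len(q_idx))
        if k:
            chosen = rng.choice(q_idx, size=k, replace=False)
            pop.state[chosen] = STATE_CYCLING
            pop.age[chosen] = 0.0
            pop.cycle_length[chosen] = np.atleast_1d(
                draw_cycle_length(schedules.T_mean(t), schedules.cv, rng, size=k)
            )


def run(config: SimConfig, rng: np.random.Generator | None = None) -> CountsTimeSeries:
    """Run one full simulation and return the recorded counts table.

    Rows are written every ``record_interval`` hours from 0 to ``t_end``
    inclusive.  Identical configs (including seed) give identical output.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = init_population(config, rng)
    protocols = tuple(config.protocols)
    n_labels = len(protocols)
    n_steps = int(round(config.t_end / config.dt))
    rec_every = max(1, int(round(config.record_interval / config.dt)))

    rows = [pop.counts_row(0.0, n_labels)]
    for k in range(n_steps):
        t = k * config.dt
        step(
            pop,
            t,
            config.dt,
            config.schedules,
            rng,
            protocols=protocols,
            phase_fractions=config.phase_fractions,
            mode_triplet=config.mode_triplet,
        )
        if (k + 1) % rec_every == 0 or k == n_steps - 1:
            rows.append(pop.counts_row((k + 1) * config.dt, n_labels))

    frame = pd.DataFrame(rows)
    # name label gates after their protocols
    renames = {f"_label{b}": f"P_{protocols[b].label_name}" for b in range(n_labels)}
    frame = frame.rename(columns=renames)
    frame = frame.drop_duplicates(subset="time_h", keep="last").reset_index(drop=True)
    return CountsTimeSeries(frame)
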