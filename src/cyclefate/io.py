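"""CSV/JSON/YAML plumbing: counts readers and writers, run manifests,
simulation configs from files, and the synthetic fixture generator."""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cellsim import (
    CountsTimeSeries,
    ScheduleSet,
    SimConfig,
    constant,
    piecewise_linear,
)
from .errors import InvalidParameterError, SchemaError

__all__ = [
    "read_counts",
    "write_counts",
    "RunManifest",
    "load_config",
    "schedule_from_spec",
    "generate_fixture",
    "FIXTURE_KINDS",
]


def read_counts(path) -> CountsTimeSeries:
    """Read a counts CSV (columns time_h, P, D required; P_cycling, Q, A
    and P_<label> gates optional).

    Decreasing D is accepted with a warning (raw data may be noisy; the
    downstream fits handle it); non-monotone time or negative counts are
    schema errors naming the offending rows.
    """
    frame = pd.read_csv(path)
    missing = [c for c in CountsTimeSeries.REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    t = frame["time_h"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        raise SchemaError(f"{path}: time_h not strictly increasing at rows {(bad + 1).tolist()}")
    num = frame.select_dtypes("number")
    neg = frame.index[(num < 0).any(axis=1)].tolist()
    if neg:
        raise SchemaError(f"{path}: negative counts in rows {neg}")
    D = frame["D"].to_numpy(dtype=float)
    if np.any(np.diff(D) < 0):
        warnings.warn(f"{path}: D decreases in places; treating as measurement noise", stacklevel=2)
    return CountsTimeSeries(frame)


def write_counts(counts: CountsTimeSeries, path) -> None:
    counts.frame.to_csv(path, index=False)


@dataclass
class RunManifest:
    """Everything needed to reproduce an output bit-for-bit."""

    command: str
    seed: int
    config: dict
    outputs: list[str] = field(default_factory=list)
    rng_algorithm: str = "PCG64"
    package_version: str = __version__
    created_utc: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def schedule_from_spec(spec) -> "callable":
    """Turn a config entry into a schedule function.

    Accepted forms: a number (constant); ``{"breakpoints": [[t, v], ...]}``
    (piecewise linear); ``{"profile": <benchmark scenario name>, "which":
    "T_mean"|"ppdd"|...}`` (named profile).
    """
    if isinstance(spec, (int, float)):
        return constant(float(spec))
    if isinstance(spec, dict):
        if "breakpoints" in spec:
            return piecewise_linear([tuple(p) for p in spec["breakpoints"]])
        if "profile" in spec:
            from .benchmark import make_scenario

            scen = make_scenario(spec["profile"])
            return getattr(scen.schedules, spec.get("which", "T_mean"))
    raise InvalidParameterError(f"cannot interpret schedule spec {spec!r}")


def load_config(path, overrides: dict | None = None) -> SimConfig:
    """Load a SimConfig from a YAML or JSON file.

    Recognized keys: initial_count, t_end, dt, seed, record_interval and a
    ``schedules`` mapping with T_mean / ppdd / gamma / apoptosis_rate / cv
    entries (constants, breakpoint lists, or named profiles).
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if overrides:
        data.update(overrides)
    sched_spec = data.pop("schedules", {})
    sched_kwargs = {}
    for key in ("T_mean", "ppdd", "gamma", "apoptosis_rate"):
        if key in sched_spec:
            sched_kwargs[key] = schedule_from_spec(sched_spec[key])
    if "cv" in sched_spec:
        sched_kwargs["cv"] = float(sched_spec["cv"])
    known = {"initial_count", "t_end", "dt", "seed", "record_interval"}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return SimConfig(schedules=ScheduleSet(**sched_kwargs), **data)


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_KINDS = ("constant", "fig2_like", "shrinking")


def _fixture_config(kind: str, seed: int) -> tuple[SimConfig, dict]:
    from .benchmark import _ramp  # shared ramp helper

    if kind == "constant":
        sched = ScheduleSet()
        truth = {"T": 20.0, "ppdd": 0.0, "gamma": 1.0, "apoptosis_rate": 0.0}
    elif kind == "fig2_like":
        # early expansion slowing into a plateau: self-renewal decays to 0
        # while the growth fraction declines, so both P and D rise
        # sigmoidally and level off
        sched = ScheduleSet(
            T_mean=constant(20.0),
            ppdd=_ramp(0.6, 0.0, 48.0),
            gamma=_ramp(1.0, 0.2, 48.0),
        )
        truth = {
            "T": 20.0,
            "ppdd": {"ramp": [0.6, 0.0]},
            "gamma": {"ramp": [1.0, 0.2]},
            "apoptosis_rate": 0.0,
        }
    elif kind == "shrinking":
        sched = ScheduleSet(ppdd=constant(-0.4))
        truth = {"T": 20.0, "ppdd": -0.4, "gamma": 1.0, "apoptosis_rate": 0.0}
    else:
        raise InvalidParameterError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    cfg = SimConfig(initial_count=500, t_end=48.0, seed=seed, schedules=sched)
    truth.update({"m": cfg.initial_count, "t_end": cfg.t_end, "seed": seed, "kind": kind})
    return cfg, truth


def generate_fixture(kind: str, seed: int = 0, out_dir=None) -> tuple[CountsTimeSeries, dict]:
    """Simulate a small counts table with known generating schedules.

    Returns (counts, truth).  With ``out_dir`` set, writes
    ``<kind>_counts.csv`` and ``<kind>_truth.json`` there.
    """
    cfg, truth = _fixture_config(kind, seed)
    from .cellsim import run

    counts = run(cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts(counts, out / f"{kind}_counts.csv")
        (out / f"{kind}_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return counts, truth
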