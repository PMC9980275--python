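"""Discrete-trial schedules and their continuous-time event streams.

Experience is segmented into trials.  Within a trial each symbol occurs at
most once; a symbol's occurrence is governed by a probability (marginal,
or conditional on other symbols occurring that trial) and its time by a
lag distribution drawn relative to an anchor (trial start or another
symbol).  Anchoring is how timing dependencies are expressed: a chain
x -> y -> z makes tau_xz = tau_xy + tau_yz trial by trial, whereas
anchoring z directly on x draws tau_xz independently of tau_xy.

Trials are rendered into an absolute-time event stream by spacing trial
starts ``span + iti`` apart.  The inter-trial interval must be long
relative to the slowest time constant of the memory (``iti >= 10/smin``)
so that, even without an explicit per-trial reset, the past state carries
a negligible shadow of the previous trial.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "LagSpec",
    "SymbolRule",
    "ScheduleSpec",
    "TrialSchedule",
    "EventStream",
    "generate_schedule",
    "schedule_to_stream",
    "read_event_stream",
    "write_event_stream",
]


@dataclass(frozen=True)
class LagSpec:
    """Distribution of a strictly positive lag.

    kind:
        ``fixed`` (constant ``value``), ``uniform_discrete`` (equiprobable
        over ``choices``) or ``gamma`` (``shape``, ``scale``).
    """

    kind: str
    value: float | None = None
    choices: tuple[float, ...] | None = None
    shape: float | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "fixed":
            if self.value is None or self.value <= 0:
                raise ValueError("fixed lag requires a positive value")
        elif self.kind == "uniform_discrete":
            if not self.choices or any(c <= 0 for c in self.choices):
                raise ValueError("uniform_discrete requires positive choices")
            object.__setattr__(self, "choices", tuple(float(c) for c in self.choices))
        elif self.kind == "gamma":
            if not self.shape or not self.scale or self.shape <= 0 or self.scale <= 0:
                raise ValueError("gamma lag requires positive shape and scale")
        else:
            raise ValueError(f"unknown lag kind {self.kind!r}")

    @staticmethod
    def fixed(value: float) -> "LagSpec":
        return LagSpec("fixed", value=value)

    @staticmethod
    def uniform(choices) -> "LagSpec":
        return LagSpec("uniform_discrete", choices=tuple(choices))

    @staticmethod
    def gamma(shape: float, scale: float) -> "LagSpec":
        return LagSpec("gamma", shape=shape, scale=scale)

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return float(self.value)
        if self.kind == "uniform_discrete":
            return float(rng.choice(self.choices))
        return float(rng.gamma(self.shape, self.scale))

    def laplace(self, s: float) -> float:
        """E[exp(-s tau)], exact; defined for negative s where the MGF exists."""
        if self.kind == "fixed":
            return math.exp(-s * self.value)
        if self.kind == "uniform_discrete":
            return float(np.mean([math.exp(-s * c) for c in self.choices]))
        # gamma MGF: E[exp(-s tau)] = (1 + s*scale)^(-shape), s > -1/scale
        if 1.0 + s * self.scale <= 0:
            raise ValueError(
                f"E[exp(-s tau)] diverges for gamma lag at s={s}")
        return float((1.0 + s * self.scale) ** (-self.shape))

    def max_support(self) -> float:
        if self.kind == "fixed":
            return float(self.value)
        if self.kind == "uniform_discrete":
            return float(max(self.choices))
        return float("inf")


@dataclass(frozen=True)
class SymbolRule:
    """Occurrence and timing rule for one symbol.

    The symbol occurs with probability ``prob`` on trials where every
    symbol in ``given`` occurred (unconditionally if ``given`` is empty),
    at the anchor's time plus a draw from ``lag``.  The anchor is the last
    symbol listed in ``given``, or the trial start.  ``lag=None`` places
    the symbol exactly at the trial start (only valid with no ``given``).
    """

    symbol: str
    prob: float = 1.0
    given: tuple[str, ...] = ()
    lag: LagSpec | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob <= 1.0):
            raise ValueError("prob must lie in [0, 1]")
        if isinstance(self.given, str):
            object.__setattr__(self, "given", (self.given,))
        else:
            object.__setattr__(self, "given", tuple(self.given))
        if self.lag is None and self.given:
            raise ValueError("a conditional symbol needs a lag distribution")


@dataclass(frozen=True)
class ScheduleSpec:
    """Declarative description of a discrete-trial world."""

    alphabet: tuple[str, ...]
    rules: tuple[SymbolRule, ...]
    n_trials: int
    iti: float = 1000.0
    smin: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        object.__setattr__(self, "rules", tuple(self.rules))
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if self.iti < 10.0 / self.smin:
            raise ValueError(
                f"iti={self.iti} is below the floor 10/smin={10.0 / self.smin}")
        seen: set[str] = set()
        for rule in self.rules:
            if rule.symbol not in self.alphabet:
                raise ValueError(f"rule symbol {rule.symbol!r} not in alphabet")
            if rule.symbol in seen:
                raise ValueError(f"duplicate rule for symbol {rule.symbol!r}")
            for g in rule.given:
                if g not in seen:
                    raise ValueError(
                        f"rule for {rule.symbol!r} references {g!r} before it "
                        "is declared (dependencies must be acyclic)")
            seen.add(rule.symbol)


@dataclass
class TrialSchedule:
    """Realized schedule: per trial, a time-sorted list of (symbol, time)."""

    spec: ScheduleSpec
    trials: list[list[tuple[str, float]]]

    @property
    def span(self) -> float:
        """Largest within-trial event time across the schedule."""
        times = [t for trial in self.trials for _, t in trial]
        return max(times) if times else 0.0


def generate_schedule(spec: ScheduleSpec) -> TrialSchedule:
    """Draw a schedule from the spec; identical seeds give identical output."""
    rng = np.random.default_rng(spec.seed)
    trials: list[list[tuple[str, float]]] = []
    for _ in range(spec.n_trials):
        placed: dict[str, float] = {}
        for rule in spec.rules:
            if any(g not in placed for g in rule.given):
                continue
            if rule.prob < 1.0 and rng.random() >= rule.prob:
                continue
            anchor = placed[rule.given[-1]] if rule.given else 0.0
            t = anchor if rule.lag is None else anchor + rule.lag.draw(rng)
            placed[rule.symbol] = t
        trial = sorted(placed.items(), key=lambda kv: kv[1])
        for (_, t0), (_, t1) in zip(trial, trial[1:]):
            if t1 <= t0:
                raise ValueError("within-trial times must be strictly increasing; "
                                 "adjust lags so symbols cannot collide")
        trials.append(trial)
    return TrialSchedule(spec, trials)


@dataclass
class EventStream:
    """Time-sorted (trial, time, symbol) records in absolute time."""

    records: pd.DataFrame  # columns: trial (int), time (float), symbol (str)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.records
        missing = {"trial", "time", "symbol"} - set(df.columns)
        if missing:
            raise FormatError(f"event stream is missing columns {sorted(missing)}")
        for trial, grp in df.groupby("trial"):
            times = grp["time"].to_numpy()
            if np.any(np.diff(times) <= 0):
                raise FormatError(f"times not strictly increasing in trial {trial}")
            dup = grp["symbol"][grp["symbol"].duplicated()]
            if len(dup):
                raise FormatError(
                    f"symbol {dup.iloc[0]!r} appears more than once in trial {trial}")

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return self.records.reset_index(drop=True).equals(
            other.records.reset_index(drop=True))

    def symbols(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.records["symbol"]))


def schedule_to_stream(sched: TrialSchedule, iti: float | None = None,
                       span: float | None = None) -> EventStream:
    """Render trials at absolute times ``trial_index * (span + iti) + t``."""
    spec = sched.spec
    if iti is None:
        iti = spec.iti
    if iti < 10.0 / spec.smin:
        raise ValueError(f"iti={iti} is below the floor 10/smin={10.0 / spec.smin}")
    if span is None:
        span = sched.span
    rows = []
    for i, trial in enumerate(sched.trials):
        start = i * (span + iti)
        for sym, t in trial:
            rows.append((i, start + t, sym))
    df = pd.DataFrame(rows, columns=["trial", "time", "symbol"])
    if df.empty:
        df = pd.DataFrame({"trial": pd.Series(dtype=int),
                           "time": pd.Series(dtype=float),
                           "symbol": pd.Series(dtype=str)})
    return EventStream(df)


def write_event_stream(stream: EventStream, path) -> None:
    """CSV (default) or JSONL depending on the file suffix."""
    path = str(path)
    df = stream.records
    if path.endswith(".jsonl"):
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                fh.write(json.dumps({"trial": int(row.trial),
                                     "time": float(row.time),
                                     "symbol": row.symbol}) + "\n")
    else:
        df.to_csv(path, index=False, float_format="%.17g")


def read_event_stream(path) -> EventStream:
    path = str(path)
    if path.endswith(".jsonl"):
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    rows.append((int(rec["trial"]), float(rec["time"]),
                                 str(rec["symbol"])))
                except (KeyError, ValueError) as exc:
                    raise FormatError(f"line {lineno}: {exc}") from exc
        df = pd.DataFrame(rows, columns=["trial", "time", "symbol"])
    else:
        df = pd.read_csv(path, dtype={"trial": int, "time": float,
                                      "symbol": str},
                         float_precision="round_trip")
    return EventStream(df)
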