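"""End-to-end driver: feed an event stream through the memory system.

On each presentation three operations run in order within one time step:
the present symbol first probes the successor weights to inject a
prediction into the future state, then the weights are updated by
associating the past with the present, and finally the symbol is encoded
into the past.  A presentation therefore never associates with itself.

Between events all states evolve exactly (the closed forms are exact in
dt), so the step size ``dt`` only quantizes when boundary arrivals are
emitted: a predicted source trips the detector at the first dt-multiple
after its rendered value at smax crosses the threshold, exactly as literal
dt-stepping would emit it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc_memory as am
from .core_manifold import (AntiTrace, ArrivalEvent, FutureState, PastState,
                            SGrid, boundary_lead_time, encode_present,
                            evolve_past, make_s_grid)
from .schedules import EventStream

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Grids and driver switches for :func:`run_experiment`.

    ``dt`` is the duration of the "present" (default 0.1 time units) and
    ``smax`` should be of order ``1/dt``.  ``reset_each_trial`` realizes
    the long-inter-trial-interval limit exactly; turn it off for demos
    that carry the past across trials.  ``track_future`` controls whether
    predictions are injected and boundary arrivals logged (turn off for
    pure learning runs).
    """

    grid: SGrid = field(default_factory=lambda: make_s_grid(0.01, 10.0, 64))
    rho: am.RhoGrid = field(default_factory=am.RhoGrid.default)
    alphabet: tuple[str, ...] | None = None
    dt: float = 0.1
    boundary_epsilon: float = 0.5
    reset_each_trial: bool = True
    track_future: bool = True
    prediction_rho_index: int = -1
    snapshots: bool = False
    snapshot_every: int = 10
    flush_after: bool = True

    @staticmethod
    def from_dict(d: dict) -> "ExperimentConfig":
        grid = make_s_grid(d.get("smin", 0.01), d.get("smax", 10.0),
                           d.get("n_s", 64))
        rho_val = d.get("rho", "default")
        rho = (am.RhoGrid.default() if rho_val == "default"
               else am.RhoGrid(np.atleast_1d(np.asarray(rho_val, dtype=float))))
        alphabet = d.get("alphabet")
        return ExperimentConfig(
            grid=grid, rho=rho,
            alphabet=tuple(alphabet) if alphabet else None,
            dt=d.get("dt", 0.1),
            boundary_epsilon=d.get("boundary_epsilon", 0.5),
            reset_each_trial=d.get("reset_each_trial", True),
            track_future=d.get("track_future", True),
            prediction_rho_index=d.get("prediction_rho_index", -1),
            snapshots=d.get("snapshots", False),
            snapshot_every=d.get("snapshot_every", 10),
            flush_after=d.get("flush_after", True))

    def to_dict(self) -> dict:
        return {"smin": self.grid.smin, "smax": self.grid.smax,
                "n_s": len(self.grid),
                "rho": [float(r) for r in self.rho.rho_values],
                "alphabet": list(self.alphabet) if self.alphabet else None,
                "dt": self.dt, "boundary_epsilon": self.boundary_epsilon,
                "reset_each_trial": self.reset_each_trial,
                "track_future": self.track_future,
                "prediction_rho_index": self.prediction_rho_index,
                "snapshots": self.snapshots,
                "snapshot_every": self.snapshot_every,
                "flush_after": self.flush_after}


@dataclass
class ExperimentResult:
    memory: am.AssocMemory
    arrivals: list[ArrivalEvent]
    snapshots: list[dict]
    past: PastState
    future: FutureState
    anti: AntiTrace

    def snapshots_to_frame(self) -> pd.DataFrame:
        """Tidy per-step log: time, kind (past/future), symbol, n, s, value."""
        rows = []
        syms = self.past.symbols
        s = self.past.grid.s_values
        for snap in self.snapshots:
            for kind in ("past", "future"):
                arr = snap[kind]
                for k, sym in enumerate(syms):
                    for n in range(arr.shape[1]):
                        rows.append((snap["time"], kind, sym, n, s[n], arr[k, n]))
        return pd.DataFrame(rows, columns=["time", "kind", "symbol", "n", "s",
                                           "value"])


def _advance_future(future: FutureState, elapsed: float, dt: float,
                    tau_c: float) -> list[ArrivalEvent]:
    """Move the predicted future forward by ``elapsed``, emitting arrivals.

    A source whose remaining time has fallen below ``tau_c`` is emitted at
    the first dt-multiple step after the crossing (identical to checking
    the detector after every literal dt step).
    """
    anchor = future.clock
    events: list[ArrivalEvent] = []
    keep = []
    eps = 1e-9
    for src in future.sources:
        n_steps = max(1, math.ceil((src.tau_rem - tau_c) / dt - eps))
        t_emit = n_steps * dt
        if t_emit <= elapsed + eps:
            events.append(ArrivalEvent(src.symbol, anchor + t_emit))
        else:
            src.tau_rem = max(src.tau_rem - elapsed, 0.0)
            keep.append(src)
    future.sources = keep
    future.clock += elapsed
    events.sort(key=lambda e: e.time)
    return events


def run_experiment(stream: EventStream, config: ExperimentConfig | None = None
                   ) -> ExperimentResult:
    """Drive the full system over an event stream and return the result.

    The returned memory, arrival log and snapshots are a pure function of
    the stream and the config.
    """
    if config is None:
        config = ExperimentConfig()
    df = stream.records
    alphabet = config.alphabet or tuple(sorted(pd.unique(df["symbol"])))
    grid, rho, dt = config.grid, config.rho, config.dt
    tau_c = boundary_lead_time(config.boundary_epsilon, grid.smax)

    mem = am.init_memory(alphabet, grid, rho)
    past = PastState(grid, alphabet)
    anti = AntiTrace(grid, alphabet)
    future = FutureState(grid, alphabet)
    arrivals: list[ArrivalEvent] = []
    snapshots: list[dict] = []
    step_count = 0

    def advance(to_time: float) -> None:
        nonlocal step_count
        elapsed = to_time - past.clock
        if elapsed < -1e-9:
            raise ValueError("event stream times must be non-decreasing")
        if elapsed <= 0:
            return
        if config.snapshots:
            # walk in dt steps so the rendered traces can be logged
            remaining = elapsed
            while remaining > 1e-12:
                # absorb float leftovers into the final step so no two
                # snapshots land at indistinguishable times
                step = dt if remaining > dt + 1e-9 else remaining
                evolve_past(past, step)
                anti.evolve(step)
                arrivals.extend(_advance_future(future, step, dt, tau_c))
                step_count += 1
                if step_count % config.snapshot_every == 0:
                    snapshots.append({"time": past.clock,
                                      "past": past.activations.copy(),
                                      "future": future.rendered})
                remaining -= step
        else:
            evolve_past(past, elapsed)
            anti.evolve(elapsed)
            arrivals.extend(_advance_future(future, elapsed, dt, tau_c))

    current_trial: int | None = None
    for rec in df.itertuples(index=False):
        trial, t, sym = int(rec.trial), float(rec.time), str(rec.symbol)
        new_trial = trial != current_trial
        advance(t)
        if new_trial:
            current_trial = trial
            if config.reset_each_trial:
                past.reset()
                anti.reset(trial_start=t)
        if config.track_future:
            pred = am.predict_future_init(mem, sym, config.prediction_rho_index)
            for src in pred.sources:
                future.add_source(src)
        am.update_on_presentation(mem, past, anti, sym)
        encode_present(past, sym)
        anti.encode(sym)

    if config.flush_after and future.sources:
        drain = max(src.tau_rem for src in future.sources) + 2 * dt
        advance(past.clock + drain)

    arrivals = _tag_not_symbols(arrivals, df, dt)
    return ExperimentResult(mem, arrivals, snapshots, past, future, anti)


def _tag_not_symbols(arrivals: list[ArrivalEvent], df: pd.DataFrame,
                     dt: float) -> list[ArrivalEvent]:
    """Retag arrivals with no matching observation within one dt.

    A "not symbol" is the pseudo-observation of a failed prediction; it is
    logged but neither learns nor predicts.
    """
    out = []
    by_symbol = {sym: grp["time"].to_numpy()
                 for sym, grp in df.groupby("symbol")}
    for ev in arrivals:
        times = by_symbol.get(ev.symbol)
        matched = times is not None and np.any(np.abs(times - ev.time)
                                               <= dt + 1e-9)
        out.append(ev if matched
                   else ArrivalEvent(ev.symbol, ev.time, kind="not_symbol"))
    return out
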