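"""Laplace-domain states for the remembered past and predicted future.

A population of units is indexed by a rate constant ``s`` sampled
geometrically between ``smax`` (nearest the present) and ``smin`` (the
longest functional time constant ``1/smin``).  For each symbol the past
state holds the real Laplace transform of the symbol's impulse history,
``F-(s) = sum_j exp(-s (t - t_j))``; the future state holds an estimate of
the Laplace transform of upcoming impulses, ``F+(s) = sum p exp(-s tau)``
with ``tau`` the remaining time until the predicted arrival.

Evolution in time is exact: receding into the past multiplies each
component by ``exp(-s dt)``; an approaching future multiplies by
``exp(+s dt)``.  The future is stored as a list of delta sources with
closed-form rendering, because literally iterating ``exp(+s dt)`` on a
stored vector is numerically explosive; the literal update is checked
against the rendering in the test suite, step by step.

Alongside the positive grid every state carries an exact ``s = 0``
channel (the transform at zero frequency is the plain impulse count),
which downstream associative weights use for probability readouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SGrid",
    "PastState",
    "AntiTrace",
    "FutureSource",
    "FutureState",
    "ArrivalEvent",
    "make_s_grid",
    "encode_present",
    "evolve_past",
    "closed_form_past",
    "evolve_future",
    "detect_and_clear_boundary",
]

# exponent cap for the mirrored (growing) trace: larger values are masked NaN
ANTI_TRACE_EXPONENT_CAP = 30.0


@dataclass(frozen=True)
class SGrid:
    """Geometric grid of rate constants, decreasing from ``smax`` to ``smin``.

    The grid index ``n`` runs from 0 at ``smax`` outward; one grid step
    corresponds to multiplying ``s`` by the constant ratio ``r < 1``, so a
    rescaling of all times by ``1/r`` translates activation patterns by
    exactly one index (scale covariance).
    """

    s_values: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s_values, dtype=float)
        object.__setattr__(self, "s_values", s)
        if s.ndim != 1 or s.size < 2:
            raise ValueError("grid needs at least two s values")
        if np.any(s <= 0):
            raise ValueError("all s values must be positive")
        if np.any(np.diff(s) >= 0):
            raise ValueError("s values must be strictly decreasing")
        ratios = s[1:] / s[:-1]
        if np.max(np.abs(ratios / ratios[0] - 1.0)) > 1e-12:
            raise ValueError("grid spacing must be geometric")

    @property
    def ratio(self) -> float:
        """Constant geometric step ``s_{n+1} / s_n`` (< 1)."""
        return float(self.s_values[1] / self.s_values[0])

    @property
    def smax(self) -> float:
        return float(self.s_values[0])

    @property
    def smin(self) -> float:
        return float(self.s_values[-1])

    def __len__(self) -> int:
        return int(self.s_values.size)


def make_s_grid(smin: float, smax: float, n: int) -> SGrid:
    """Geometric grid of ``n`` rate constants from ``smax`` down to ``smin``."""
    if not (0 < smin < smax):
        raise ValueError("require 0 < smin < smax")
    if n < 2:
        raise ValueError("grid needs at least two points")
    return SGrid(np.geomspace(smax, smin, int(n)))


def _symbol_index(symbols: tuple[str, ...], symbol: str) -> int:
    try:
        return symbols.index(symbol)
    except ValueError:
        raise ValueError(f"unknown symbol {symbol!r}; alphabet is {symbols}") from None


@dataclass
class PastState:
    """Per-symbol Laplace transform of the impulse history up to ``clock``.

    ``activations[k, n]`` is symbol ``k``'s component at grid point ``n``;
    ``zero_s[k]`` is the exact value at ``s = 0`` (the impulse count).
    """

    grid: SGrid
    symbols: tuple[str, ...]
    activations: np.ndarray = field(default=None)  # type: ignore[assignment]
    zero_s: np.ndarray = field(default=None)  # type: ignore[assignment]
    clock: float = 0.0

    def __post_init__(self) -> None:
        self.symbols = tuple(self.symbols)
        if self.activations is None:
            self.activations = np.zeros((len(self.symbols), len(self.grid)))
        if self.zero_s is None:
            self.zero_s = np.zeros(len(self.symbols))

    def index(self, symbol: str) -> int:
        return _symbol_index(self.symbols, symbol)

    def vector(self, symbol: str) -> np.ndarray:
        return self.activations[self.index(symbol)]

    def copy(self) -> "PastState":
        return PastState(self.grid, self.symbols, self.activations.copy(),
                         self.zero_s.copy(), self.clock)

    def reset(self) -> "PastState":
        self.activations[:] = 0.0
        self.zero_s[:] = 0.0
        return self

    def to_frame(self) -> pd.DataFrame:
        """Tidy snapshot with columns symbol, n, s, value."""
        k, n = self.activations.shape
        return pd.DataFrame({
            "symbol": np.repeat(self.symbols, n),
            "n": np.tile(np.arange(n), k),
            "s": np.tile(self.grid.s_values, k),
            "value": self.activations.ravel(),
        })


def encode_present(state: PastState, symbol: str) -> PastState:
    """Add the transform of an impulse at the present (1 at every s)."""
    i = state.index(symbol)
    state.activations[i] += 1.0
    state.zero_s[i] += 1.0
    return state


def evolve_past(state: PastState, dt: float) -> PastState:
    """Recede the stored past by ``dt``: multiply by ``exp(-s dt)``."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt > 0:
        state.activations *= np.exp(-state.grid.s_values * dt)
    state.clock += dt
    return state


def closed_form_past(impulse_times: dict[str, list[float]], t: float,
                     grid: SGrid, symbols: tuple[str, ...] | None = None) -> PastState:
    """Analytic oracle: superposed decayed impulses at time ``t``.

    The entry for a symbol at grid point ``s`` is ``sum_j exp(-s (t - t_j))``,
    against which any sequence of encode/evolve steps can be checked.
    """
    if symbols is None:
        symbols = tuple(impulse_times)
    state = PastState(grid, symbols, clock=t)
    for sym, times in impulse_times.items():
        i = state.index(sym)
        for tj in times:
            if tj > t:
                raise ValueError(f"impulse time {tj} is in the future of t={t}")
            state.activations[i] += np.exp(-grid.s_values * (t - tj))
            state.zero_s[i] += 1.0
    return state


@dataclass
class AntiTrace:
    """Within-trial mirrored trace ``sum_j exp(+s (t - t_j))``, reset each trial.

    This grows without bound, so it is rendered lazily from the stored
    impulse times; entries whose exponent exceeds ``ANTI_TRACE_EXPONENT_CAP``
    are masked NaN and excluded downstream.  It is the carrier for learning
    the mirrored (-s) half of the predecessor weights.
    """

    grid: SGrid
    symbols: tuple[str, ...]
    clock: float = 0.0
    trial_start: float = 0.0
    _times: dict[int, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = tuple(self.symbols)

    def index(self, symbol: str) -> int:
        return _symbol_index(self.symbols, symbol)

    def encode(self, symbol: str) -> "AntiTrace":
        self._times.setdefault(self.index(symbol), []).append(self.clock)
        return self

    def evolve(self, dt: float) -> "AntiTrace":
        if dt < 0:
            raise ValueError("dt must be non-negative")
        self.clock += dt
        return self

    def reset(self, trial_start: float | None = None) -> "AntiTrace":
        self._times.clear()
        if trial_start is not None:
            self.trial_start = trial_start
        return self

    @property
    def activations(self) -> np.ndarray:
        """(symbols, grid) array of growing exponentials; NaN where capped."""
        out = np.zeros((len(self.symbols), len(self.grid)))
        s = self.grid.s_values
        for i, times in self._times.items():
            for tj in times:
                expo = s * (self.clock - tj)
                term = np.where(expo <= ANTI_TRACE_EXPONENT_CAP, np.exp(np.minimum(expo, ANTI_TRACE_EXPONENT_CAP)), np.nan)
                out[i] = out[i] + term
        return out

    @property
    def zero_s(self) -> np.ndarray:
        out = np.zeros(len(self.symbols))
        for i, times in self._times.items():
            out[i] = len(times)
        return out


@dataclass
class FutureSource:
    """A predicted delta: symbol arrives with weight ``p`` in ``tau_rem``."""

    symbol: str
    weight: float
    tau_rem: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("source weight must lie in [0, 1]")
        if self.tau_rem < 0:
            raise ValueError("remaining time must be non-negative")


@dataclass(frozen=True)
class ArrivalEvent:
    """A prediction that reached the present (tau -> 0)."""

    symbol: str
    time: float
    kind: str = "observed"  # retagged "not_symbol" if no observation matches


@dataclass
class FutureState:
    """Predicted future as a list of delta sources with closed-form rendering."""

    grid: SGrid
    symbols: tuple[str, ...]
    sources: list[FutureSource] = field(default_factory=list)
    clock: float = 0.0

    def __post_init__(self) -> None:
        self.symbols = tuple(self.symbols)

    def index(self, symbol: str) -> int:
        return _symbol_index(self.symbols, symbol)

    def add_source(self, source: FutureSource) -> "FutureState":
        _symbol_index(self.symbols, source.symbol)
        self.sources.append(source)
        return self

    @property
    def rendered(self) -> np.ndarray:
        """(symbols, grid) array: ``sum_sources p exp(-s tau_rem)`` per symbol."""
        out = np.zeros((len(self.symbols), len(self.grid)))
        s = self.grid.s_values
        for src in self.sources:
            out[self.index(src.symbol)] += src.weight * np.exp(-s * src.tau_rem)
        return out

    def vector(self, symbol: str) -> np.ndarray:
        return self.rendered[self.index(symbol)]

    def to_frame(self) -> pd.DataFrame:
        rend = self.rendered
        k, n = rend.shape
        return pd.DataFrame({
            "symbol": np.repeat(self.symbols, n),
            "n": np.tile(np.arange(n), k),
            "s": np.tile(self.grid.s_values, k),
            "value": rend.ravel(),
        })


def evolve_future(state: FutureState, dt: float) -> FutureState:
    """Bring the predicted future closer by ``dt``.

    Each source's remaining time decreases by ``dt``; equivalently the
    rendered vector is multiplied by ``exp(+s dt)`` wherever the source has
    not yet reached the present.  Sources that would cross tau = 0 within
    ``dt`` must be cleared by :func:`detect_and_clear_boundary` first.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    for src in state.sources:
        if src.tau_rem < dt:
            raise InvalidBoundaryError(
                f"source {src.symbol!r} reaches the present within dt={dt}; "
                "handle the boundary before evolving")
    for src in state.sources:
        src.tau_rem -= dt
    state.clock += dt
    return state


class InvalidBoundaryError(RuntimeError):
    """The tau = 0 boundary was crossed without being handled."""


def boundary_lead_time(epsilon: float, smax: float) -> float:
    """Remaining time below which a unit source trips the boundary detector."""
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must lie in (0, 1)")
    return -math.log(epsilon) / smax


def detect_and_clear_boundary(state: FutureState, epsilon: float
                              ) -> tuple[FutureState, list[ArrivalEvent]]:
    """Emit arrivals for sources whose rendered value at ``smax`` exceeds
    ``epsilon`` of their weight, and subtract their full contribution.

    The detector watches the largest available rate constant as the proxy
    for ``s -> infinity``, which only rises from zero as a prediction
    approaches the present.
    """
    tau_c = boundary_lead_time(epsilon, state.grid.smax)
    events: list[ArrivalEvent] = []
    keep: list[FutureSource] = []
    for src in state.sources:
        # exp(-smax * tau_rem) > epsilon  <=>  tau_rem < -ln(eps)/smax
        if src.tau_rem < tau_c:
            events.append(ArrivalEvent(src.symbol, state.clock))
        else:
            keep.append(src)
    state.sources = keep
    return state, events
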