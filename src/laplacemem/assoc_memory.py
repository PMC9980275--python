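"""Hebbian successor and predecessor weights over (rho, s).

``M[rho, s, y, x]`` associates a source symbol x in the Laplace past with a
target symbol y arriving in the present/future.  When a symbol is
presented:

* every connection *from* that symbol decays by rho (it was re-presented,
  so its prior history is discounted), and
* the connections *to* that symbol increment by ``(1 - rho) * F-(s)``,
  the current Laplace past.

In the rho -> 1 limit the steady state is ``M_yx(s) = P(y|x) E[exp(-s
tau_xy)]``: the conditional probability times the Laplace transform of the
lag distribution (its moment-generating function at -s).  No temporal
difference bootstrapping is involved; the multiscale past acts as a
spectrum of eligibility traces.

The mirrored predecessor weights ``Mbar[rho, +-s, x, y]`` condition the
past symbol x on the present symbol y; both halves of the signed s axis
are learned in one pass, the -s half from the within-trial growing trace
(see :class:`~laplacemem.core_manifold.AntiTrace`).  Entries whose growing
exponent overflows the trace's cap are NaN and excluded downstream.

A continuum of forgetting rates rho turns each weight into the Z-transform
of its trial history (see :mod:`laplacemem.trial_history`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_manifold import AntiTrace, FutureSource, PastState, SGrid
from .schedules import LagSpec

__all__ = [
    "RhoGrid",
    "AssocMemory",
    "PredictionInit",
    "init_memory",
    "update_on_presentation",
    "predict_future_init",
    "steady_state_oracle",
]


@dataclass(frozen=True)
class RhoGrid:
    """Increasing forgetting rates in the open interval (0, 1)."""

    rho_values: np.ndarray

    def __post_init__(self) -> None:
        r = np.atleast_1d(np.asarray(self.rho_values, dtype=float))
        object.__setattr__(self, "rho_values", r)
        if np.any((r <= 0) | (r >= 1)):
            raise ValueError("rho values must lie strictly inside (0, 1)")
        if r.size > 1 and np.any(np.diff(r) <= 0):
            raise ValueError("rho values must be strictly increasing")

    @staticmethod
    def default(n: int = 24, lr_max: float = 0.5, lr_min: float = 0.002) -> "RhoGrid":
        """Geometric in the learning rate 1 - rho, from lr_max down to lr_min."""
        return RhoGrid(1.0 - np.geomspace(lr_max, lr_min, n))

    @staticmethod
    def single(rho: float) -> "RhoGrid":
        return RhoGrid(np.array([rho]))

    def __len__(self) -> int:
        return int(self.rho_values.size)

    def nearest_index(self, rho: float) -> int:
        return int(np.argmin(np.abs(self.rho_values - rho)))


@dataclass
class AssocMemory:
    """Successor and predecessor weights plus their exact s = 0 channel.

    Shapes: ``M`` is (n_rho, N, targets, sources); ``Mbar`` is
    (n_rho, 2N, past, present) with the first N entries at +s (grid order)
    and the last N mirrored at -s.  ``M0``/``Mbar0`` hold the s = 0
    readout, learned online from impulse counts, used wherever a
    probability (zero-frequency) value is required exactly.
    """

    symbols: tuple[str, ...]
    grid: SGrid
    rho: RhoGrid
    M: np.ndarray = field(default=None)  # type: ignore[assignment]
    Mbar: np.ndarray = field(default=None)  # type: ignore[assignment]
    M0: np.ndarray = field(default=None)  # type: ignore[assignment]
    Mbar0: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.symbols = tuple(self.symbols)
        if not self.symbols:
            raise ValueError("alphabet must be non-empty")
        k, n, r = len(self.symbols), len(self.grid), len(self.rho)
        if self.M is None:
            self.M = np.zeros((r, n, k, k))
        if self.Mbar is None:
            self.Mbar = np.zeros((r, 2 * n, k, k))
        if self.M0 is None:
            self.M0 = np.zeros((r, k, k))
        if self.Mbar0 is None:
            self.Mbar0 = np.zeros((r, k, k))

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise ValueError(f"unknown symbol {symbol!r}") from None

    @property
    def signed_s_values(self) -> np.ndarray:
        s = self.grid.s_values
        return np.concatenate([s, -s])

    # readout helpers -----------------------------------------------------
    def successor_row(self, rho_index: int, target: str, source: str) -> np.ndarray:
        """M_target,source over the s grid at one rho."""
        return self.M[rho_index, :, self.index(target), self.index(source)]

    def predecessor_row(self, rho_index: int, past: str, present: str,
                        mirrored: bool = False) -> np.ndarray:
        """Mbar_past,present over +s (or -s when mirrored) at one rho."""
        n = len(self.grid)
        half = slice(n, 2 * n) if mirrored else slice(0, n)
        return self.Mbar[rho_index, half, self.index(past), self.index(present)]

    def successor_at_zero(self, rho_index: int, target: str, source: str) -> float:
        return float(self.M0[rho_index, self.index(target), self.index(source)])

    def predecessor_at_zero(self, rho_index: int, past: str, present: str) -> float:
        return float(self.Mbar0[rho_index, self.index(past), self.index(present)])

    def copy(self) -> "AssocMemory":
        return AssocMemory(self.symbols, self.grid, self.rho, self.M.copy(),
                           self.Mbar.copy(), self.M0.copy(), self.Mbar0.copy())

    # export ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Tidy successor weights: rho, s, target, source, value."""
        r, n, k, _ = self.M.shape
        rho = self.rho.rho_values
        idx = np.indices((r, n, k, k))
        return pd.DataFrame({
            "rho": rho[idx[0].ravel()],
            "s": self.grid.s_values[idx[1].ravel()],
            "target": np.asarray(self.symbols)[idx[2].ravel()],
            "source": np.asarray(self.symbols)[idx[3].ravel()],
            "value": self.M.ravel(),
        })

    def save(self, path) -> None:
        """Compact binary container; bit-exact round trip via :meth:`load`."""
        np.savez(path,
                 index_order=np.array(["rho", "s", "target", "source"]),
                 symbols=np.array(self.symbols),
                 s_values=self.grid.s_values,
                 rho_values=self.rho.rho_values,
                 M=self.M, Mbar=self.Mbar, M0=self.M0, Mbar0=self.Mbar0)

    @classmethod
    def load(cls, path) -> "AssocMemory":
        with np.load(path, allow_pickle=False) as data:
            return cls(tuple(str(s) for s in data["symbols"]),
                       SGrid(data["s_values"]), RhoGrid(data["rho_values"]),
                       data["M"].copy(), data["Mbar"].copy(),
                       data["M0"].copy(), data["Mbar0"].copy())


def init_memory(alphabet, grid: SGrid, rho: RhoGrid) -> AssocMemory:
    """All-zero weights with the declared index order."""
    return AssocMemory(tuple(alphabet), grid, rho)


def update_on_presentation(mem: AssocMemory, past: PastState, anti: AntiTrace,
                           symbol: str) -> AssocMemory:
    """Apply one presentation: decay, then Hebbian increment, at every rho.

    ``past`` and ``anti`` must reflect the state *before* the presented
    symbol is encoded (the presentation associates with the past, never
    with itself).
    """
    j = mem.index(symbol)
    if abs(past.clock - anti.clock) > 1e-6:
        raise ValueError("past state and anti trace are out of register")
    rho = mem.rho.rho_values
    lr = 1.0 - rho
    n = len(mem.grid)

    F = past.activations.T  # (N, symbols)
    A = anti.activations.T
    F0 = past.zero_s
    A0 = anti.zero_s

    # successor: connections from the presented symbol decay ...
    mem.M[:, :, :, j] *= rho[:, None, None]
    mem.M0[:, :, j] *= rho[:, None]
    # ... then connections to it are strengthened by the current past
    mem.M[:, :, j, :] += lr[:, None, None] * F[None, :, :]
    mem.M0[:, j, :] += lr[:, None] * F0[None, :]

    # predecessor: the presented symbol's column decays and is incremented
    # by the past at +s and by the mirrored trace at -s
    mem.Mbar[:, :, :, j] *= rho[:, None, None]
    mem.Mbar0[:, :, j] *= rho[:, None]
    mem.Mbar[:, :n, :, j] += lr[:, None, None] * F[None, :, :]
    mem.Mbar[:, n:, :, j] += lr[:, None, None] * A[None, :, :]
    mem.Mbar0[:, :, j] += lr[:, None] * F0[None, :]
    return mem


@dataclass
class PredictionInit:
    """Decoded initialization for the predicted future after a presentation."""

    rows: dict[str, np.ndarray]        # target -> M_target,source(rho, s) row
    sources: list[FutureSource]
    multimodal: set[str] = field(default_factory=set)
    fit_residuals: dict[str, float] = field(default_factory=dict)


def _fit_delta(row: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    """Fit p*exp(-s*tau) by least squares on log(row); exact on exponentials.

    Returns (p, tau, relative residual).
    """
    pos = row > 0
    if pos.sum() < 2:
        p = float(row[pos][0]) if pos.any() else 0.0
        return p, 0.0, 0.0
    logm = np.log(row[pos])
    slope, intercept = np.polyfit(s[pos], logm, 1)
    tau = max(-float(slope), 0.0)
    p = float(np.exp(intercept))
    pred = p * np.exp(-s * tau)
    resid = float(np.linalg.norm(row - pred) / np.linalg.norm(row))
    return p, tau, resid


def predict_future_init(mem: AssocMemory, symbol: str, rho_index: int,
                        mode: str = "fit",
                        rng: np.random.Generator | None = None,
                        residual_tol: float = 0.10) -> PredictionInit:
    """Probe the successor weights with the present symbol.

    Returns, per target with nonzero weight, the raw Laplace row
    ``M_target,symbol(rho, s)`` and a delta source ``(target, p, tau)``.
    The weight p comes from the exact s = 0 channel when available and the
    delay from a log-linear fit of the row, which is exact when the row is
    the transform of a single delta.  Rows whose relative fit residual
    exceeds ``residual_tol`` are flagged multi-modal; in ``mode="sample"``
    their delay is drawn from the decoded delay distribution instead
    (requires ``rng``).
    """
    if mode not in ("fit", "sample"):
        raise ValueError("mode must be 'fit' or 'sample'")
    j = mem.index(symbol)
    s = mem.grid.s_values
    out = PredictionInit(rows={}, sources=[])
    for t_idx, target in enumerate(mem.symbols):
        row = mem.M[rho_index, :, t_idx, j]
        if not np.any(row > 0):
            continue
        out.rows[target] = row.copy()
        p0 = mem.M0[rho_index, t_idx, j]
        p_fit, tau, resid = _fit_delta(row, s)
        p = float(p0) if p0 > 0 else p_fit
        out.fit_residuals[target] = resid
        if resid > residual_tol:
            out.multimodal.add(target)
            if mode == "sample":
                if rng is None:
                    raise ValueError("mode='sample' requires an rng")
                tau = _sample_delay(row, mem.grid, rng)
        out.sources.append(FutureSource(target, min(p, 1.0), tau))
    return out


def _sample_delay(row: np.ndarray, grid: SGrid, rng: np.random.Generator) -> float:
    """Draw a delay from the inverse-space density decoded from the row."""
    from .inverse_space import InverseConfig, post_inverse

    cfg = InverseConfig()
    dens = post_inverse(row, grid, cfg)
    tau_star = cfg.tau_star_values(grid)
    total = dens.sum()
    if total <= 0:
        return float(tau_star[len(tau_star) // 2])
    return float(rng.choice(tau_star, p=dens / total))


def steady_state_oracle(P: float, lag: LagSpec, s: float) -> float:
    """rho -> 1 fixed point of the learning rule: ``P * E[exp(-s tau)]``.

    Valid for any real s where the lag distribution's moment-generating
    function exists (negative s probes the mirrored predecessor half).
    """
    if not (0.0 <= P <= 1.0):
        raise ValueError("P must lie in [0, 1]")
    return P * lag.laplace(s)
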