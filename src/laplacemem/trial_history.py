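"""Trial-history memory across the continuum of forgetting rates.

With a spectrum of rho, each learned weight is the Z-transform of its
trial history evaluated at 1/rho:

    M_yx(rho, s) = (1 - rho) * sum_i rho^i h[i] exp(-s tau[i]),

where i counts presentations of the source symbol backwards from the most
recent, h[i] marks whether the target followed on that trial and tau[i]
is the lag when it did.  Although each fixed rho forgets exponentially,
the profile across rho retains the whole history; on a finite rho grid it
is inverted by non-negative least squares against the geometric design
matrix A[m, i] = (1 - rho_m) rho_m^i (histories are non-negative and
sparse, which is exactly where NNLS recovery is reliable).

Combining the rho axis with the inverse-space transform over s yields a
two-dimensional image over (trial lag, log time-within-trial), and
decoded histories of two weights sharing a present symbol support
three-point (triplet) correlations across trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr

from .assoc_memory import AssocMemory, RhoGrid
from .errors import UndefinedCorrelationError
from .inverse_space import InverseConfig, post_inverse

__all__ = [
    "TrialHistory",
    "HistoryDecode",
    "HistoryImage",
    "ztransform_forward",
    "design_matrix",
    "decode_trial_history",
    "history_image",
    "three_point_history_correlation",
]


@dataclass
class TrialHistory:
    """Indicator h[i] and lag tau[i] per trial i steps back (i = 0 newest)."""

    h: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=int)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.h.shape != self.tau.shape:
            raise ValueError("h and tau must have the same length")
        if np.any((self.h != 0) & (self.h != 1)):
            raise ValueError("h must be a 0/1 indicator")

    @property
    def horizon(self) -> int:
        return int(self.h.size)

    @staticmethod
    def from_pairings(pairings: dict[int, float], horizon: int) -> "TrialHistory":
        """Build from {trial lag: lag time} for the trials where h = 1."""
        h = np.zeros(horizon, dtype=int)
        tau = np.full(horizon, np.nan)
        for i, t in pairings.items():
            h[i] = 1
            tau[i] = t
        return TrialHistory(h, tau)


def ztransform_forward(hist: TrialHistory, rho: float, s: float = 0.0) -> float:
    """(1 - rho) * sum_i rho^i h[i] exp(-s tau[i]).

    This closed form equals the weight produced by running the Hebbian
    decay/increment rule over the same trial sequence, exactly.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must lie in (0, 1)")
    idx = np.nonzero(hist.h)[0]
    if idx.size == 0:
        return 0.0
    return float((1.0 - rho) * np.sum(rho ** idx * np.exp(-s * hist.tau[idx])))


def design_matrix(rho_values: np.ndarray, horizon: int) -> np.ndarray:
    """A[m, i] = (1 - rho_m) rho_m^i for trial lags i = 0..horizon."""
    rho = np.asarray(rho_values, dtype=float)
    i = np.arange(horizon + 1)
    return (1.0 - rho)[:, None] * rho[:, None] ** i[None, :]


@dataclass
class HistoryDecode:
    """Non-negative trial-lag weights recovered from a rho profile."""

    weights: np.ndarray
    residual: float
    condition_number: float

    @property
    def argmax_lag(self) -> int:
        # ties break toward the smallest lag (argmax returns first maximum)
        return int(np.argmax(self.weights))


def decode_trial_history(profile: np.ndarray, rho: RhoGrid, horizon: int = 20
                         ) -> HistoryDecode:
    """Invert the Z-transform profile over rho by non-negative least squares.

    Requires at least ``horizon`` rho values for identifiability.  The
    design-matrix condition number is reported because recovery degrades
    quickly once measurement noise is added to the profile.
    """
    profile = np.asarray(profile, dtype=float)
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if len(rho) < horizon:
        raise ValueError(
            f"rho grid has {len(rho)} values; need >= horizon={horizon}")
    if not np.all(np.isfinite(profile)):
        raise ValueError("profile must be finite")
    A = design_matrix(rho.rho_values, horizon)
    weights, rnorm = nnls(A, profile)
    return HistoryDecode(weights, float(rnorm), float(np.linalg.cond(A)))


@dataclass
class HistoryImage:
    """Decoded (trial lag, log within-trial time) image of one weight row."""

    matrix: np.ndarray          # (horizon + 1, n tau*)
    trial_lags: np.ndarray
    tau_star: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        lags, taus = self.matrix.shape
        return pd.DataFrame({
            "trial_lag": np.repeat(self.trial_lags, taus),
            "tau_star": np.tile(self.tau_star, lags),
            "value": self.matrix.ravel(),
        })

    @property
    def argmax(self) -> tuple[int, int]:
        """(trial-lag index, tau* index) of the strongest cell."""
        i = int(np.argmax(self.matrix))
        return np.unravel_index(i, self.matrix.shape)  # type: ignore[return-value]


def history_image(mem: AssocMemory, x: str, y: str, horizon: int = 20,
                  cfg: InverseConfig | None = None) -> HistoryImage:
    """Unfold M_yx(rho, s) into trial lag (via rho) and time (via s).

    Each rho row is pushed through the inverse transform to a profile over
    tau*, then each tau* column is decoded across rho.  A single pairing
    tau0 one trial back shows up as a blob at (trial lag 1, tau* near
    tau0 k/(k+1)); further source-alone trials shift it to larger lags
    without moving it along the time axis.
    """
    if cfg is None:
        cfg = InverseConfig()
    rows = mem.M[:, :, mem.index(y), mem.index(x)]  # (rho, s)
    if not np.any(rows > 0):
        n_tau = len(mem.grid)
        return HistoryImage(np.zeros((horizon + 1, n_tau)),
                            np.arange(horizon + 1),
                            cfg.tau_star_values(mem.grid))
    fields = np.vstack([post_inverse(row, mem.grid, cfg) for row in rows])
    out = np.zeros((horizon + 1, fields.shape[1]))
    for col in range(fields.shape[1]):
        out[:, col] = decode_trial_history(fields[:, col], mem.rho, horizon).weights
    return HistoryImage(out, np.arange(horizon + 1),
                        cfg.tau_star_values(mem.grid))


def three_point_history_correlation(mem: AssocMemory, x: str, y: str, z: str,
                                    horizon: int = 20,
                                    use_decoded: bool = True) -> float:
    """Correlate z's and x's trial histories, both conditioned on y.

    M_zy(rho, s=0) stores which recent y-trials were followed by z;
    Mbar_xy(rho, s=0) stores which were preceded by x.  If z occurs only
    when x and y co-occur, the decoded histories coincide on y-trials and
    correlate positively.  ``use_decoded=False`` correlates the raw rho
    profiles instead of the decoded lag weights.

    The decode's final lag absorbs all history beyond the horizon (it is
    the tail of the geometric design), so it is not an estimate of any
    single trial and is excluded from the correlation.
    """
    prof_direct = mem.M0[:, mem.index(z), mem.index(y)]
    prof_pred = mem.Mbar0[:, mem.index(x), mem.index(y)]
    if use_decoded:
        a = decode_trial_history(prof_direct, mem.rho, horizon).weights[:horizon]
        b = decode_trial_history(prof_pred, mem.rho, horizon).weights[:horizon]
    else:
        a, b = prof_direct, prof_pred
    if _near_constant(a) or _near_constant(b):
        raise UndefinedCorrelationError(
            "decoded history has zero variance; correlation undefined")
    return float(pearsonr(a, b).statistic)


def _near_constant(v: np.ndarray, rel: float = 1e-6) -> bool:
    return bool(np.std(v) <= rel * (np.abs(np.mean(v)) + 1e-12))
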