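"""Contingency: should credit for z go to the candidate y or a mediator x?

Direct prediction ``M_zy(s)`` holds the Laplace transform of the y-to-z
delay.  The mediated product ``M_zx(s) * Mbar_xy(-s)`` chains the future
of z predicted by x with the past occurrence of x recovered from y; it
equals the transform of the *convolution* of the x-to-z delay with the
reversed x-to-y delay.  The two coincide exactly when the delays are
independent across trials (the transform of a sum of independent
variables factorizes), so their log-ratio across s measures temporal
dependence; at s = 0 the same comparison reduces to conditional
probabilities, P(z|y) versus P(z|x) P(x|y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc_memory import AssocMemory
from .errors import InvalidStateError

__all__ = ["ContingencyReport", "associative_contingency", "temporal_contingency"]

LOG_RATIO_FLOOR = 1e-12
# fraction of a curve's maximum below which grid points are excluded from
# the divergence: deep in the exponential tail the log-ratio of two
# finite-sample estimates is dominated by sampling noise
RELATIVE_CURVE_FLOOR = 0.05


@dataclass
class ContingencyReport:
    """Direct vs mediated prediction of z from y, with a credit verdict."""

    direct: float | np.ndarray
    mediated: float | np.ndarray
    divergence: float
    credit: str  # mediator_x | candidate_y | indeterminate
    tolerance: float
    s_values: np.ndarray | None = None
    valid: np.ndarray | None = None
    symbols: tuple[str, str, str] | None = None  # (x, y, z)

    def to_frame(self) -> pd.DataFrame:
        if self.s_values is None:
            return pd.DataFrame({"s": [0.0], "direct": [self.direct],
                                 "mediated": [self.mediated]})
        return pd.DataFrame({"s": self.s_values,
                             "direct": np.atleast_1d(self.direct),
                             "mediated": np.atleast_1d(self.mediated),
                             "valid": np.atleast_1d(self.valid)})

    def verdict(self) -> dict:
        return {"credit": self.credit, "divergence": self.divergence,
                "tolerance": self.tolerance,
                "symbols": list(self.symbols) if self.symbols else None}


def _log_divergence(direct: np.ndarray, mediated: np.ndarray) -> np.ndarray:
    d = np.maximum(np.asarray(direct, dtype=float), LOG_RATIO_FLOOR)
    m = np.maximum(np.asarray(mediated, dtype=float), LOG_RATIO_FLOOR)
    return np.abs(np.log(d / m))


def _credit(divergence: float, tolerance: float) -> str:
    return "mediator_x" if divergence <= tolerance else "candidate_y"


def associative_contingency(mem: AssocMemory, x: str, y: str, z: str,
                            rho_index: int = -1, tolerance: float = 0.05
                            ) -> ContingencyReport:
    """Compare P(z|y) with P(z|x) P(x|y) using the smallest-s proxy for s = 0.

    The proxy bias is ``|exp(-smin tau) - 1| <= smin * tau_max`` per factor;
    with the default grid (smin = 0.01) and single-digit lags it is under
    2% and largely cancels in the ratio.
    """
    if len({x, y, z}) != 3:
        raise ValueError("x, y, z must be three distinct symbols")
    direct = float(mem.successor_row(rho_index, z, y)[-1])
    mediated = float(mem.successor_row(rho_index, z, x)[-1]
                     * mem.predecessor_row(rho_index, x, y)[-1])
    trained = (np.any(mem.successor_row(rho_index, z, y) > 0)
               or (np.any(mem.successor_row(rho_index, z, x) > 0)
                   and np.any(mem.predecessor_row(rho_index, x, y) > 0)))
    if not trained:
        warnings.warn("contingency on untrained rows is indeterminate",
                      stacklevel=2)
        return ContingencyReport(direct, mediated, 0.0, "indeterminate",
                                 tolerance, symbols=(x, y, z))
    div = float(_log_divergence(np.array([direct]), np.array([mediated]))[0])
    return ContingencyReport(direct, mediated, div, _credit(div, tolerance),
                             tolerance, symbols=(x, y, z))


def temporal_contingency(mem: AssocMemory, x: str, y: str, z: str,
                         rho_index: int = -1, tolerance: float = 0.05,
                         min_valid: int = 5,
                         relative_floor: float = RELATIVE_CURVE_FLOOR
                         ) -> ContingencyReport:
    """Compare the full curves M_zy(+s) and M_zx(+s) * Mbar_xy(-s).

    Grid points are valid when the mirrored predecessor entry is finite
    (not masked by the growing-trace cap) and both curves retain at least
    ``relative_floor`` of their maximum.  Divergence is the maximum
    absolute log-ratio over valid points; equality within tolerance is the
    signature of independent delays.
    """
    if len({x, y, z}) != 3:
        raise ValueError("x, y, z must be three distinct symbols")
    s = mem.grid.s_values
    direct = mem.successor_row(rho_index, z, y).astype(float)
    mediated = (mem.successor_row(rho_index, z, x)
                * mem.predecessor_row(rho_index, x, y, mirrored=True))
    valid = np.isfinite(mediated) & np.isfinite(direct)
    if np.any(valid) and np.any(direct[valid] > 0) and np.any(mediated[valid] > 0):
        valid &= direct >= relative_floor * np.nanmax(direct[valid])
        valid &= mediated >= relative_floor * np.nanmax(mediated[valid])
    else:
        valid &= False
    if valid.sum() < min_valid:
        raise InvalidStateError(
            f"only {int(valid.sum())} valid mirrored grid points; "
            f"need at least {min_valid}")
    div = float(np.max(_log_divergence(direct[valid], mediated[valid])))
    return ContingencyReport(direct, mediated, div, _credit(div, tolerance),
                             tolerance, s_values=s, valid=valid,
                             symbols=(x, y, z))
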