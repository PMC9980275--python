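"""Canonical study conditions as ready-made schedule specs.

These are the conditioning-style worlds the package is exercised on: a cue
``x`` opens each trial and other symbols follow it with fixed,
discrete-uniform or gamma-distributed lags.  Defaults (trial counts,
probabilities, lags, forgetting rates) are the conditions under which the
learned weights are compared against their closed forms; they are chosen
so the exponentially weighted learning has effectively converged while a
desk-scale run stays in seconds.
"""

from __future__ import annotations

from .schedules import (LagSpec, ScheduleSpec, SymbolRule, TrialSchedule,
                        generate_schedule, schedule_to_stream)

__all__ = [
    "deterministic_pairing",
    "probabilistic_pairing",
    "gamma_lag_pairing",
    "independent_chain",
    "dependent_chain",
    "triplet_conjunction",
    "triplet_null",
    "fan_out_delays",
]


def deterministic_pairing(n_trials: int = 500, lag: float = 3.0,
                          seed: int = 0) -> ScheduleSpec:
    """y follows x on every trial at a fixed lag (the saturation world)."""
    return ScheduleSpec(
        ("x", "y"),
        (SymbolRule("x"), SymbolRule("y", 1.0, ("x",), LagSpec.fixed(lag))),
        n_trials, seed=seed)


def probabilistic_pairing(p: float = 0.8, n_trials: int = 2000,
                          lag: float = 3.0, seed: int = 0) -> ScheduleSpec:
    """y follows x with probability p; M_yx(s=0) estimates p."""
    return ScheduleSpec(
        ("x", "y"),
        (SymbolRule("x"), SymbolRule("y", p, ("x",), LagSpec.fixed(lag))),
        n_trials, seed=seed)


def gamma_lag_pairing(n_trials: int = 5000, shape: float = 2.0,
                      scale: float = 1.0, seed: int = 0) -> ScheduleSpec:
    """Deterministic pairing with gamma-distributed lags; the normalized
    weight curve estimates the lag distribution's transform (1+s*scale)^-shape."""
    return ScheduleSpec(
        ("x", "y"),
        (SymbolRule("x"),
         SymbolRule("y", 1.0, ("x",), LagSpec.gamma(shape, scale))),
        n_trials, seed=seed)


def independent_chain(n_trials: int = 5000, seed: int = 0) -> ScheduleSpec:
    """x, then y and z each timed off x with independent lags.

    tau_xy ~ U{1,2} and tau_xz ~ U{5,6} are independent draws, so the
    direct and mediated contingency curves coincide.
    """
    return ScheduleSpec(
        ("x", "y", "z"),
        (SymbolRule("x"),
         SymbolRule("y", 1.0, ("x",), LagSpec.uniform((1.0, 2.0))),
         SymbolRule("z", 1.0, ("x",), LagSpec.uniform((5.0, 6.0)))),
        n_trials, seed=seed)


def dependent_chain(n_trials: int = 5000, seed: int = 0) -> ScheduleSpec:
    """x -> y -> z chain: tau_xz = tau_xy + 3 trial by trial.

    tau_xy ~ U{1,2}; z follows y at a fixed lag of 3, making the y-to-z
    timing deterministic and the x-to-z timing dependent on tau_xy.
    """
    return ScheduleSpec(
        ("x", "y", "z"),
        (SymbolRule("x"),
         SymbolRule("y", 1.0, ("x",), LagSpec.uniform((1.0, 2.0))),
         SymbolRule("z", 1.0, ("y",), LagSpec.fixed(3.0))),
        n_trials, seed=seed)


def triplet_conjunction(n_trials: int = 500, seed: int = 0) -> ScheduleSpec:
    """x and y occur independently (p = 0.5 each); z iff both occurred."""
    return ScheduleSpec(
        ("x", "y", "z"),
        (SymbolRule("x", 0.5),
         SymbolRule("y", 0.5, (), LagSpec.fixed(2.0)),
         SymbolRule("z", 1.0, ("x", "y"), LagSpec.fixed(3.0))),
        n_trials, seed=seed)


def triplet_null(n_trials: int = 500, seed: int = 0) -> ScheduleSpec:
    """As the conjunction world, but z follows y at random, blind to x."""
    return ScheduleSpec(
        ("x", "y", "z"),
        (SymbolRule("x", 0.5),
         SymbolRule("y", 0.5, (), LagSpec.fixed(2.0)),
         SymbolRule("z", 0.5, ("y",), LagSpec.fixed(3.0))),
        n_trials, seed=seed)


def fan_out_delays(taus: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0),
                   n_trials: int = 400) -> TrialSchedule:
    """Round-robin cues cs_i each predicting the outcome r at its own delay.

    The learned weight to r as a function of the cue's delay falls off as
    exp(-s tau) at every grid rate s.
    """
    alphabet = tuple(f"cs{i}" for i in range(len(taus))) + ("r",)
    spec = ScheduleSpec(alphabet, (SymbolRule("r", 0.0),), 0)
    trials = [[(f"cs{t % len(taus)}", 0.0), ("r", taus[t % len(taus)])]
              for t in range(n_trials)]
    return TrialSchedule(spec, trials)


def stream_for(spec_or_sched, **kwargs):
    """Convenience: realize a spec (or pass a schedule through) as a stream."""
    if isinstance(spec_or_sched, ScheduleSpec):
        spec_or_sched = generate_schedule(spec_or_sched)
    return schedule_to_stream(spec_or_sched, **kwargs)
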