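"""Explicit Euler integration with auto-adaptive sub-stepping.

The solver advances any ODE system with forward-Euler steps whose size is
chosen per step: starting from the user timestep ``base_step`` the
candidate step is halved until no state variable would change by more than
``frac_threshold`` (10% by default) of its current magnitude in a single
update, with an absolute floor ``abs_floor`` so that variables sitting near
zero do not pin the step, and a hard lower bound ``h_min`` on the step
itself.  If even ``h_min`` violates the threshold the step is taken anyway
and flagged — the solution may "jitter" around its trend but the solver
does not stall.

Sampling takes the value computed during the step whose time interval
contains the requested sample time; no interpolation is performed.
Negative concentrations produced by an overshooting step are clamped to
zero and counted.  The scheme is deterministic: identical inputs give
bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["IntegratorSettings", "adaptive_step", "integrate", "IntegrationResult"]


@dataclass(frozen=True)
class IntegratorSettings:
    """Step-control parameters of the adaptive Euler scheme.

    ``base_step`` (s) is the upper bound on any accepted step;
    ``frac_threshold`` the maximum fractional per-step change of any state
    variable; ``h_min`` (s) the lower bound on the step; ``abs_floor`` the
    absolute change below which the fractional test is waived; ``t_end``
    (s) the default time span; ``max_steps`` a safety cap that marks the
    run unstable instead of looping forever at ``h_min``.
    """

    base_step: float = 1.0
    frac_threshold: float = 0.10
    h_min: float = 1e-10
    abs_floor: float = 1e-12
    t_end: float = 720_000.0
    max_steps: int = 50_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.h_min <= self.base_step:
            raise ValueError("require 0 < h_min <= base_step")
        if not 0.0 < self.frac_threshold < 1.0:
            raise ValueError("frac_threshold must lie in (0, 1)")
        if self.abs_floor < 0:
            raise ValueError("abs_floor must be nonnegative")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")


def _choose_step(
    y: np.ndarray, dydt: np.ndarray, settings: IntegratorSettings
) -> tuple[float, bool]:
    """Largest halved step satisfying the per-variable change threshold.

    Returns ``(h, floored)``; ``floored`` is True when even the smallest
    admissible step violates the threshold (the step is then taken at that
    size regardless).
    """
    limit = np.maximum(settings.frac_threshold * np.abs(y), settings.abs_floor)
    h = settings.base_step
    while True:
        if np.all(np.abs(h * dydt) <= limit):
            return h, False
        if h * 0.5 < settings.h_min:
            return h, True
        h *= 0.5


def adaptive_step(
    y: np.ndarray,
    rhs_fn: Callable[[np.ndarray], np.ndarray],
    settings: IntegratorSettings,
) -> tuple[np.ndarray, float, bool]:
    """One adaptive Euler step from state ``y``.

    Evaluates the derivative once (for an explicit Euler update the trial
    change scales linearly with ``h``, so halving never needs a re-
    evaluation), picks the largest admissible halved step, and returns
    ``(y_next, h, floored)``.

    Raises ``FloatingPointError`` if the derivative is non-finite, so the
    caller can propagate an instability signal.
    """
    y = np.asarray(y, dtype=float)
    dydt = np.asarray(rhs_fn(y), dtype=float)
    if not np.all(np.isfinite(dydt)):
        raise FloatingPointError("non-finite derivative")
    h, floored = _choose_step(y, dydt, settings)
    return y + h * dydt, h, floored


@dataclass
class IntegrationResult:
    """Sampled trajectory of a generic adaptive-Euler run."""

    sample_times: np.ndarray          # requested times, s
    step_times: np.ndarray            # end time of the recording step, s
    y: np.ndarray                     # state at each sample, shape (n, dim)
    stable: bool
    n_steps: int
    n_clamped: int
    n_floored: int
    events: list = field(default_factory=list)


def integrate(
    rhs_fn: Callable[[np.ndarray], np.ndarray],
    y0: Sequence[float],
    settings: IntegratorSettings,
    sample_times: Sequence[float],
    positive_indices: Sequence[int] = (),
    clamp_negative: bool = True,
) -> IntegrationResult:
    """Integrate ``dy/dt = rhs_fn(y)`` from t=0, recording at sample times.

    ``positive_indices`` lists components whose nonpositivity marks the run
    unstable (e.g. the chain-end concentration, whose vanishing would mean
    every molecule closed into a ring).  Other components driven negative
    by an overshooting step are clamped to zero when ``clamp_negative`` is
    set.  An unstable run is returned flagged, with NaN rows for the
    samples never reached — never raised, since least-squares fitting needs
    the flagged result.
    """
    y = np.asarray(y0, dtype=float).copy()
    times = np.asarray(sample_times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("sample_times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample_times must be strictly increasing")
    n = times.size
    out = np.full((n, y.size), np.nan)
    step_t = np.full(n, np.nan)
    stable = True
    n_steps = n_clamped = n_floored = 0
    events: list = []
    t = 0.0
    idx = 0
    while idx < n and times[idx] <= 0.0:
        out[idx] = y
        step_t[idx] = t
        idx += 1
    while idx < n:
        if n_steps >= settings.max_steps:
            stable = False
            events.append(("max_steps", t))
            break
        dydt = np.asarray(rhs_fn(y), dtype=float)
        if not np.all(np.isfinite(dydt)):
            stable = False
            events.append(("nonfinite_derivative", t))
            break
        h, floored = _choose_step(y, dydt, settings)
        if floored:
            n_floored += 1
        y_new = y + h * dydt
        if not np.all(np.isfinite(y_new)):
            stable = False
            events.append(("nonfinite_state", t))
            break
        neg = y_new < 0.0
        if clamp_negative and np.any(neg):
            fatal = [i for i in positive_indices if neg[i]]
            if fatal:
                stable = False
                events.append(("nonpositive", t, tuple(fatal)))
                break
            n_clamped += int(np.count_nonzero(neg))
            y_new[neg] = 0.0
        if any(y_new[i] <= 0.0 for i in positive_indices):
            stable = False
            events.append(("nonpositive", t))
            break
        t += h
        y = y_new
        n_steps += 1
        while idx < n and times[idx] <= t + 1e-9:
            out[idx] = y
            step_t[idx] = t
            idx += 1
    return IntegrationResult(
        sample_times=times,
        step_times=step_t,
        y=out,
        stable=stable,
        n_steps=n_steps,
        n_clamped=n_clamped,
        n_floored=n_floored,
        events=events,
    )
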