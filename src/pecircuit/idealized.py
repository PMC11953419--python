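"""Idealized prediction-error dynamics.

The reduced model keeps only the computational essence of a prediction-error
(PE) circuit: a negative PE rate ``r_n = [r_m - s]_+`` and a positive PE rate
``r_p = [s - r_m]_+`` drive a memory unit (a perfect integrator whose steady
state is the exponential moving average of the input) and a variance unit
(a leaky integrator with quadratic activation whose steady state is the
variance of the input).  It serves both as a fast simulation mode and as an
analytic oracle for the full circuit model: the closed-form piecewise
exponential solution of the memory equation (:func:`ema_closed_form`) is
exact for piecewise-constant stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IdealizedParams",
    "IdealizedState",
    "idealized_pe_rates",
    "step_idealized",
    "ema_closed_form",
    "simulate_idealized",
]


@dataclass(frozen=True)
class IdealizedParams:
    """Time constants of the idealized model, in milliseconds.

    ``tau_m`` is the effective memory time constant.  In the circuit model the
    memory neuron integrates gain-normalized PE rates with weight
    ``lambda/g``, so its effective constant is ``tau_E / lambda``; use that
    value here when comparing modes.  ``tau_v`` is the leak constant of the
    variance unit (5 s in the full model).
    """

    tau_m: float = 60.0 / 4.5e-2
    tau_v: float = 5000.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.tau_v <= 0:
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class IdealizedState:
    """Memory rate, variance rate and time of the idealized model."""

    r_m: float = 0.0
    r_v: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.r_m):
            raise ValueError("r_m must be finite")
        if self.r_v < 0:
            raise ValueError("r_v must be non-negative")


def idealized_pe_rates(r_m: float, s: float) -> tuple[float, float]:
    """Rectified negative/positive PE rates for memory ``r_m`` and input ``s``.

    Returns ``(r_n, r_p)`` with ``r_n = [r_m - s]_+`` and ``r_p = [s - r_m]_+``.
    At most one of the two is nonzero (complementarity).
    """
    d = r_m - s
    return (max(d, 0.0), max(-d, 0.0))


def _rhs(r_m: float, r_v: float, s: float, p: IdealizedParams) -> tuple[float, float]:
    r_n, r_p = idealized_pe_rates(r_m, s)
    d_m = (r_p - r_n) / p.tau_m
    d_v = (-r_v + (r_p + r_n) ** 2) / p.tau_v
    return d_m, d_v


def step_idealized(
    state: IdealizedState, s: float, dt: float, params: IdealizedParams
) -> IdealizedState:
    """Advance the idealized model one explicit second-order Runge-Kutta step.

    Heun's method: both stage evaluations rectify the PE rates, matching the
    integration of the full circuit.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    k1m, k1v = _rhs(state.r_m, state.r_v, s, params)
    k2m, k2v = _rhs(state.r_m + dt * k1m, state.r_v + dt * k1v, s, params)
    r_m = state.r_m + 0.5 * dt * (k1m + k2m)
    r_v = max(state.r_v + 0.5 * dt * (k1v + k2v), 0.0)
    return IdealizedState(r_m=r_m, r_v=r_v, t=state.t + dt)


def ema_closed_form(
    segments: Sequence[tuple[float, float]],
    tau_m: float,
    r_m0: float = 0.0,
) -> np.ndarray:
    """Exact memory trajectory at segment boundaries for piecewise-constant input.

    ``segments`` is a sequence of ``(value, duration_ms)`` pairs.  Within each
    segment the memory equation is linear, so
    ``r_m(t0 + T) = c + (r_m(t0) - c) * exp(-T / tau_m)`` for segment value
    ``c``.  Returns the array of memory values *after* each segment,
    length ``len(segments)``.  This is the independent oracle for both
    :func:`step_idealized` and the circuit-mode memory neuron.
    """
    if len(segments) == 0:
        raise ValueError("need at least one segment")
    if tau_m <= 0:
        raise ValueError("tau_m must be positive")
    out = np.empty(len(segments))
    r = float(r_m0)
    for i, (c, T) in enumerate(segments):
        if T <= 0:
            raise ValueError("segment durations must be positive")
        r = c + (r - c) * np.exp(-T / tau_m)
        out[i] = r
    return out


def simulate_idealized(
    stimulus: Iterable[float],
    dt: float,
    params: IdealizedParams,
    state: IdealizedState | None = None,
) -> np.ndarray:
    """Integrate the idealized model over a per-step stimulus array.

    Returns an ``(n, 2)`` array of ``(r_m, r_v)`` after each step.
    """
    if state is None:
        state = IdealizedState()
    stim = np.asarray(list(stimulus) if not isinstance(stimulus, np.ndarray) else stimulus, float)
    out = np.empty((stim.size, 2))
    for i, s in enumerate(stim):
        state = step_idealized(state, float(s), dt, params)
        out[i, 0] = state.r_m
        out[i, 1] = state.r_v
    return out
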