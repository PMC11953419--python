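"""Stimulation protocols: seeded, piecewise-constant stimulus series.

A protocol describes a two-timescale stimulus.  Each of ``n_trials`` trials
has a mean ``mu_in`` drawn from a uniform distribution U(a, b) (trial-to-trial
variability, with mean ``(a+b)/2`` and standard deviation ``(b-a)/sqrt(12)``)
or held fixed.  Within a trial the stimulus is a sequence of ``n_values``
constant values drawn from a normal (default) or moment-matched uniform
distribution around ``mu_in`` with variance ``sigma2_in`` (stimulus noise);
each value is presented for ``steps_per_value`` time steps of 1 ms.

Negative values from the normal family are kept as drawn (no clipping); the
rendered series records their frequency so protocols operating close to zero
can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "StimulusProtocol",
    "StimulusSeries",
    "uniform_from_moments",
    "draw_trial_means",
    "draw_stimulus_values",
    "render_protocol",
    "get_preset",
    "PRESETS",
]

Family = Literal["normal", "uniform"]

DT_MS = 1.0  # one time step of the rendered series


def uniform_from_moments(mu: float, sigma2: float) -> tuple[float, float]:
    """Bounds (a, b) of the uniform distribution with mean ``mu`` and variance ``sigma2``.

    Inverts mean = (a+b)/2, sd = (b-a)/sqrt(12): a,b = mu -+ sqrt(3*sigma2).
    """
    if sigma2 < 0:
        raise ValueError("variance must be non-negative")
    half = math.sqrt(3.0 * sigma2)
    return (mu - half, mu + half)


@dataclass(frozen=True)
class StimulusProtocol:
    """Trial structure and distribution specification of one stimulation protocol.

    ``trial_mean`` is either a float (fixed mean in every trial) or a pair
    ``(a, b)`` of uniform bounds from which the mean is re-drawn each trial.
    ``scalar_variability`` optionally sets the within-trial standard deviation
    to ``k * mu_in`` (overriding ``sigma2_in``), emulating scalar variability
    of magnitude estimation.
    """

    n_trials: int
    n_values: int
    steps_per_value: int
    trial_mean: float | tuple[float, float]
    sigma2_in: float = 0.0
    family: Family = "normal"
    scalar_variability: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_values < 1 or self.steps_per_value < 1:
            raise ValueError("n_trials, n_values and steps_per_value must be >= 1")
        if self.sigma2_in < 0:
            raise ValueError("sigma2_in must be non-negative")
        if isinstance(self.trial_mean, tuple):
            a, b = self.trial_mean
            if a > b:
                raise ValueError("uniform bounds must satisfy a <= b")
        if self.family not in ("normal", "uniform"):
            raise ValueError(f"unknown family {self.family!r}")

    # -- derived quantities -------------------------------------------------
    @property
    def trial_duration_ms(self) -> float:
        return self.n_values * self.steps_per_value * DT_MS

    @property
    def n_steps(self) -> int:
        return self.n_trials * self.n_values * self.steps_per_value

    @property
    def mu_trial(self) -> float:
        if isinstance(self.trial_mean, tuple):
            a, b = self.trial_mean
            return 0.5 * (a + b)
        return float(self.trial_mean)

    @property
    def sigma2_trial(self) -> float:
        if isinstance(self.trial_mean, tuple):
            a, b = self.trial_mean
            return (b - a) ** 2 / 12.0
        return 0.0

    @classmethod
    def from_variances(
        cls,
        n_trials: int,
        n_values: int,
        steps_per_value: int,
        mu_trial: float,
        sigma2_trial: float,
        sigma2_in: float,
        **kwargs,
    ) -> "StimulusProtocol":
        """Construct a protocol from (mu_trial, sigma2_trial) instead of bounds."""
        bounds = uniform_from_moments(mu_trial, sigma2_trial)
        trial_mean: float | tuple[float, float]
        trial_mean = mu_trial if sigma2_trial == 0 else bounds
        return cls(n_trials, n_values, steps_per_value, trial_mean,
                   sigma2_in=sigma2_in, **kwargs)


@dataclass(frozen=True)
class StimulusSeries:
    """A rendered protocol: per-step values plus the trial bookkeeping."""

    values: np.ndarray          # (n_steps,)
    trial_means: np.ndarray     # (n_trials,)
    trial_index: np.ndarray     # (n_steps,) int
    steps_per_trial: int
    dt_ms: float = DT_MS

    @property
    def n_trials(self) -> int:
        return self.trial_means.size

    @property
    def negative_fraction(self) -> float:
        """Fraction of time steps with a negative stimulus value."""
        return float(np.mean(self.values < 0.0))

    def to_frame(self, stride: int = 1) -> pd.DataFrame:
        idx = np.arange(0, self.values.size, stride)
        return pd.DataFrame(
            {"time_ms": idx * self.dt_ms, "value": self.values[idx]}
        )


def draw_trial_means(protocol: StimulusProtocol, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_trials`` i.i.d. trial means from the protocol's uniform spec."""
    if not isinstance(protocol.trial_mean, tuple):
        raise ValueError("protocol has a fixed trial mean; nothing to draw")
    a, b = protocol.trial_mean
    return rng.uniform(a, b, protocol.n_trials)


def draw_stimulus_values(
    mean: float,
    sigma2: float,
    n: int,
    family: Family = "normal",
    k: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. within-trial stimulus values.

    With ``k`` set (scalar variability) the standard deviation is ``k * mean``,
    overriding ``sigma2``.  The uniform family matches the first two moments.
    """
    if sigma2 < 0:
        raise ValueError("variance must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    if k is not None:
        sigma2 = (k * mean) ** 2
    if sigma2 == 0:
        return np.full(n, float(mean))
    if family == "normal":
        return mean + math.sqrt(sigma2) * rng.standard_normal(n)
    a, b = uniform_from_moments(mean, sigma2)
    return rng.uniform(a, b, n)


def render_protocol(protocol: StimulusProtocol, seed: int | None = None) -> StimulusSeries:
    """Render a protocol to a piecewise-constant series.

    The global seed spawns independent streams for the trial means and the
    within-trial values, so changing ``n_trials`` or within-trial noise does
    not reshuffle the other component.  Identical protocol + seed gives a
    bit-identical series.
    """
    if seed is None:
        seed = protocol.seed
    ss = np.random.SeedSequence(seed)
    rng_means, rng_values = (np.random.default_rng(s) for s in ss.spawn(2))

    if isinstance(protocol.trial_mean, tuple):
        means = draw_trial_means(protocol, rng_means)
    else:
        means = np.full(protocol.n_trials, float(protocol.trial_mean))

    vals = np.empty((protocol.n_trials, protocol.n_values))
    for i, m in enumerate(means):
        vals[i] = draw_stimulus_values(
            m, protocol.sigma2_in, protocol.n_values, protocol.family,
            protocol.scalar_variability, rng_values,
        )
    values = np.repeat(vals.ravel(), protocol.steps_per_value)
    steps_per_trial = protocol.n_values * protocol.steps_per_value
    trial_index = np.repeat(np.arange(protocol.n_trials), steps_per_trial)
    return StimulusSeries(values=values, trial_means=means,
                          trial_index=trial_index, steps_per_trial=steps_per_trial)


# ---------------------------------------------------------------------------
# Protocol presets, one per row of the stimulation-parameter table.
# Sweep entries ("[x, y]") are exposed through the experiment drivers; the
# presets below pin the example/limit-case conditions.
# ---------------------------------------------------------------------------

def _p(**kw) -> StimulusProtocol:
    return StimulusProtocol(**kw)


PRESETS: dict[str, StimulusProtocol] = {
    # Single 100-s run of 200 values; mean/variance estimation worked example.
    # Stated example moments mu_in = 5, sigma2_in = 4; uniform family.
    "fig2DE": _p(n_trials=1, n_values=200, steps_per_value=500,
                 trial_mean=5.0, sigma2_in=4.0, family="uniform"),
    # Noise-free stimuli, volatile environment (sensory-dominated limit).
    "fig3C": _p(n_trials=100, n_values=10, steps_per_value=500,
                trial_mean=(1.0, 9.0), sigma2_in=0.0),
    # Noisy stimuli, stable environment (prediction-dominated limit).
    "fig3D": _p(n_trials=100, n_values=10, steps_per_value=500,
                trial_mean=(5.0, 5.0), sigma2_in=5.0),
    # Base condition of the variance grid (both variances 5).
    "fig3E": StimulusProtocol.from_variances(
        n_trials=100, n_values=10, steps_per_value=500,
        mu_trial=5.0, sigma2_trial=5.0, sigma2_in=5.0),
    # Within-trial time course, 5-s and 1-s trials.
    "fig3F_5s": StimulusProtocol.from_variances(
        n_trials=100, n_values=10, steps_per_value=500,
        mu_trial=5.0, sigma2_trial=9.0, sigma2_in=5.0),
    "fig3F_1s": StimulusProtocol.from_variances(
        n_trials=100, n_values=10, steps_per_value=100,
        mu_trial=5.0, sigma2_trial=9.0, sigma2_in=5.0),
    # Perturbation regimes (modulation applied in the last 100 of 200 trials):
    # sensory-driven (noise-free stimuli, volatile means) and
    # prediction-driven (noisy stimuli, stable mean).
    "fig4_sensory": StimulusProtocol.from_variances(
        n_trials=200, n_values=10, steps_per_value=500,
        mu_trial=5.0, sigma2_trial=1.0, sigma2_in=0.0),
    "fig4_prediction": _p(n_trials=200, n_values=10, steps_per_value=500,
                          trial_mean=(5.0, 5.0), sigma2_in=1.0),
    # Contraction bias: two stimulus uncertainties over U(15, 25) trial means.
    "fig5A_low": _p(n_trials=200, n_values=10, steps_per_value=500,
                    trial_mean=(15.0, 25.0), sigma2_in=1.0),
    "fig5A_high": _p(n_trials=200, n_values=10, steps_per_value=500,
                     trial_mean=(15.0, 25.0), sigma2_in=4.0),
    # Zero stimulus noise, two trial-to-trial variabilities.
    "fig5C_narrow": _p(n_trials=200, n_values=10, steps_per_value=500,
                       trial_mean=(15.0, 25.0), sigma2_in=0.0),
    "fig5C_wide": _p(n_trials=200, n_values=10, steps_per_value=500,
                     trial_mean=(10.0, 30.0), sigma2_in=0.0),
    # Zero trial-to-trial variability, two stimulus noise levels.
    "fig5D_low": _p(n_trials=200, n_values=10, steps_per_value=500,
                    trial_mean=15.0, sigma2_in=4.0),
    "fig5D_high": _p(n_trials=200, n_values=10, steps_per_value=500,
                     trial_mean=15.0, sigma2_in=25.0),
}


def get_preset(name: str, **overrides) -> StimulusProtocol:
    """Look up a named protocol preset, optionally overriding fields."""
    try:
        proto = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return replace(proto, **overrides) if overrides else proto
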