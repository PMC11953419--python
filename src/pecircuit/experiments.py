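"""Experiment designs and their summary statistics.

Drivers for the standard protocols: mean/variance estimation runs, variance
grids over the two uncertainty axes, within-trial time-resolved sensory
weights, neuromodulatory (interneuron) perturbation experiments, and the
contraction-bias analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .circuit import PerturbationSpec
from .network import (
    HierarchyNetwork,
    build_network,
    sensory_weight,
    simulate_network,
    weighted_output,
)
from .stimuli import StimulusProtocol, StimulusSeries, render_protocol

__all__ = [
    "SimulationResult",
    "BiasResult",
    "run_simulation",
    "steady_state_alpha",
    "sweep_variance_grid",
    "time_resolved_alpha",
    "perturbation_experiment",
    "compute_bias",
    "bias_factor_sweeps",
]

log = logging.getLogger(__name__)


@dataclass
class SimulationResult:
    """Time-indexed record of a full network simulation.

    ``summary`` columns are (r_M_low, r_V_low, r_M_high, r_V_high) at every
    step; ``alpha`` and ``r_out`` are computed arithmetically per step.
    ``rates`` optionally holds the 16 circuit rates at ``rates_stride``
    resolution (lower circuit first, unit order as in ``circuit.UNITS``).
    """

    stimulus: StimulusSeries
    summary: np.ndarray
    alpha: np.ndarray
    r_out: np.ndarray
    protocol: StimulusProtocol
    seed: int | None
    variant: str
    lambda_low: float
    lambda_high: float
    pert: PerturbationSpec | None = None
    rates: np.ndarray | None = None
    rates_stride: int = 0
    counters: dict = field(default_factory=dict)
    dt_ms: float = 1.0

    @property
    def r_m_low(self) -> np.ndarray:
        return self.summary[:, 0]

    @property
    def r_v_low(self) -> np.ndarray:
        return self.summary[:, 1]

    @property
    def r_m_high(self) -> np.ndarray:
        return self.summary[:, 2]

    @property
    def r_v_high(self) -> np.ndarray:
        return self.summary[:, 3]

    def to_frame(self, stride: int = 10) -> pd.DataFrame:
        idx = np.arange(0, self.summary.shape[0], stride)
        return pd.DataFrame({
            "time_ms": idx * self.dt_ms,
            "stimulus": self.stimulus.values[idx],
            "trial": self.stimulus.trial_index[idx],
            "r_m_low": self.summary[idx, 0],
            "r_v_low": self.summary[idx, 1],
            "r_m_high": self.summary[idx, 2],
            "r_v_high": self.summary[idx, 3],
            "alpha": self.alpha[idx],
            "r_out": self.r_out[idx],
        })


def run_simulation(
    network: HierarchyNetwork,
    protocol: StimulusProtocol,
    pert: PerturbationSpec | None = None,
    seed: int | None = None,
    dt: float = 1.0,
    rates_stride: int = 0,
) -> SimulationResult:
    """Render the protocol, integrate the network from zero rates, score it."""
    series = render_protocol(protocol, seed=seed)
    if series.negative_fraction > 0:
        log.debug("stimulus series has %.2f%% negative values",
                  100 * series.negative_fraction)
    onset = None
    if pert is not None:
        onset = pert.onset_trial * series.steps_per_trial
    summary, rates, counters = simulate_network(
        network, series.values, pert=pert, onset_step=onset, dt=dt,
        rates_stride=rates_stride)
    alpha = sensory_weight(summary[:, 1], summary[:, 3])
    r_out = weighted_output(series.values, summary[:, 0], alpha)
    return SimulationResult(
        stimulus=series, summary=summary, alpha=alpha, r_out=r_out,
        protocol=protocol, seed=seed, variant=network.variant,
        lambda_low=network.lambda_low, lambda_high=network.lambda_high,
        pert=pert, rates=rates if rates_stride else None,
        rates_stride=rates_stride, counters=counters, dt_ms=dt)


def steady_state_alpha(
    result_or_summary,
    window: tuple[float, float] = (0.5, 1.0),
    method: str = "ratio_of_means",
) -> float:
    """Summary sensory weight over a fractional time window of the run.

    ``method="ratio_of_means"`` (default) applies the weighting formula once
    to the time-averaged variance rates, which estimates the steady-state
    weight without the Jensen bias that averaging the instantaneous ratio
    incurs when the variance rates fluctuate.  ``method="mean_alpha"``
    averages the per-step ratio instead.
    """
    if isinstance(result_or_summary, SimulationResult):
        summary = result_or_summary.summary
    else:
        summary = np.asarray(result_or_summary)
    n = summary.shape[0]
    sl = slice(int(window[0] * n), int(window[1] * n))
    if method == "ratio_of_means":
        return float(sensory_weight(summary[sl, 1].mean(), summary[sl, 3].mean()))
    if method == "mean_alpha":
        return float(np.mean(sensory_weight(summary[sl, 1], summary[sl, 3])))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Variance grid
# ---------------------------------------------------------------------------

def sweep_variance_grid(
    network: HierarchyNetwork,
    sigma2_in_values: Sequence[float],
    sigma2_trial_values: Sequence[float],
    n_trials: int = 100,
    n_values: int = 10,
    steps_per_value: int = 500,
    mu_trial: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Steady-state sensory weight per (sigma2_in, sigma2_trial) cell.

    Each cell is an independent seeded run; a failed cell is recorded with a
    NaN weight and its error message, and the sweep continues.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sigma2_in_values) * len(sigma2_trial_values))
    k = 0
    for s2_in in sigma2_in_values:
        for s2_tr in sigma2_trial_values:
            cell_seed = int(children[k].generate_state(1)[0] % (2 ** 31))
            k += 1
            try:
                proto = StimulusProtocol.from_variances(
                    n_trials, n_values, steps_per_value,
                    mu_trial=mu_trial, sigma2_trial=s2_tr, sigma2_in=s2_in)
                res = run_simulation(network, proto, seed=cell_seed)
                rows.append(dict(sigma2_in=s2_in, sigma2_trial=s2_tr,
                                 seed=cell_seed,
                                 alpha=steady_state_alpha(res), error=""))
            except Exception as exc:  # keep sweeping
                log.error("cell (%s, %s) failed: %s", s2_in, s2_tr, exc)
                rows.append(dict(sigma2_in=s2_in, sigma2_trial=s2_tr,
                                 seed=cell_seed, alpha=np.nan, error=str(exc)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Time-resolved sensory weight
# ---------------------------------------------------------------------------

def time_resolved_alpha(
    result: SimulationResult,
    discard_frac: float = 0.5,
) -> pd.DataFrame:
    """Mean +- SEM of the sensory weight aligned to trial onset.

    Transient trials (the first ``discard_frac`` of the run) are excluded;
    at least 10 analysed trials are required.
    """
    series = result.stimulus
    n_trials = series.n_trials
    spt = series.steps_per_trial
    if n_trials * spt != result.alpha.size:
        raise ValueError("result lacks a consistent trial structure")
    first = int(np.ceil(discard_frac * n_trials))
    kept = result.alpha.reshape(n_trials, spt)[first:]
    if kept.shape[0] < 10:
        raise ValueError("need at least 10 trials after discarding transients")
    mean = kept.mean(axis=0)
    sem = kept.std(axis=0, ddof=1) / np.sqrt(kept.shape[0])
    return pd.DataFrame({
        "time_in_trial_ms": np.arange(spt) * result.dt_ms,
        "alpha_mean": mean,
        "alpha_sem": sem,
    })


# ---------------------------------------------------------------------------
# Interneuron perturbation experiments
# ---------------------------------------------------------------------------

REGIME_PROTOCOLS = {
    # sensory-driven: noise-free stimuli, mildly volatile trial means
    "sensory": dict(sigma2_in=0.0, sigma2_trial=1.0, mu_trial=5.0),
    # prediction-driven: noisy stimuli, fixed trial mean
    "prediction": dict(sigma2_in=1.0, sigma2_trial=0.0, mu_trial=5.0),
}


def perturbation_experiment(
    network: HierarchyNetwork,
    regime: str,
    target_sets: Sequence[tuple[str, ...]] = (("PV",), ("SOM",), ("VIP",), ("SOM", "VIP")),
    strengths: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_trials: int = 200,
    n_values: int = 10,
    steps_per_value: int = 500,
    scope: str = "both",
    seed: int = 0,
) -> pd.DataFrame:
    """Sensory-weight shift versus modulation strength per interneuron target set.

    The perturbation (equal extra excitatory input to every listed target)
    starts at the midpoint trial.  The modulated weight is measured over the
    last quarter of the run; the reference is an unperturbed control run of
    the same protocol and seed, scored over the same window, so slow
    convergence of the higher-level memory neuron cancels out of the shift.
    """
    if regime not in REGIME_PROTOCOLS:
        raise ValueError(f"unknown regime {regime!r}")
    for ts in target_sets:
        for t in ts:
            if t not in ("PV", "SOM", "VIP"):
                raise ValueError(f"unknown perturbation target {t!r}")
    spec = REGIME_PROTOCOLS[regime]
    proto = StimulusProtocol.from_variances(
        n_trials, n_values, steps_per_value, **spec)
    onset_trial = n_trials // 2
    window = (0.75, 1.0)

    def window_stats(res):
        n = res.summary.shape[0]
        sl = slice(int(window[0] * n), int(window[1] * n))
        v_sum = res.summary[sl, 1].mean() + res.summary[sl, 3].mean()
        return steady_state_alpha(res, window=window), v_sum

    control = run_simulation(network, proto, seed=seed)
    a_control, v_control = window_stats(control)
    rows = []
    for ts in target_sets:
        for strength in strengths:
            if strength == 0.0:
                a_pert, v_pert = a_control, v_control
            else:
                pert = PerturbationSpec(targets={t: strength for t in ts},
                                        scope=scope, onset_trial=onset_trial)
                res = run_simulation(network, proto, pert=pert, seed=seed)
                a_pert, v_pert = window_stats(res)
            rows.append(dict(regime=regime, targets="+".join(ts),
                             strength=strength, scope=scope, seed=seed,
                             alpha_base=a_control, alpha_pert=a_pert,
                             delta_alpha=a_pert - a_control,
                             # summed variance signal left relative to the
                             # unperturbed run; near zero means the PE
                             # population is silenced and the weighting
                             # ratio is no longer informative
                             v_signal_frac=v_pert / v_control
                             if v_control > 0 else np.nan))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Contraction bias
# ---------------------------------------------------------------------------

@dataclass
class BiasResult:
    """Per-trial contraction bias and its linear fit against the trial mean."""

    table: pd.DataFrame      # columns: trial, mu_in, bias
    slope: float
    intercept: float

    @property
    def magnitude(self) -> float:
        """|m|: absolute slope of bias versus trial mean."""
        return abs(self.slope)


def compute_bias(
    result: SimulationResult,
    discard_frac: float = 0.25,
    trial_window: tuple[float, float] = (0.0, 1.0),
    against: str = "stimulus",
) -> BiasResult:
    """Contraction bias: trial-averaged weighted output minus the trial stimulus.

    The bias of a trial is the average of ``r_out - s`` over the trial (or
    over the fractional ``trial_window`` of it, e.g. (0.8, 1.0) for the
    settled tail).  A least-squares line of bias against the trial stimulus
    quantifies the pull toward the distribution mean: the bias is positive
    below and negative above it, and |slope| measures its strength.

    ``against`` selects the regressor: the trial's realized mean stimulus
    (``"stimulus"``, default - defined even when the trial means are not
    re-drawn, where the bias is driven purely by stimulus noise) or the
    drawn trial mean (``"mu_in"``).  Raises if the regressor is degenerate
    (all values identical), since the slope is undefined then.
    """
    series = result.stimulus
    n_trials = series.n_trials
    spt = series.steps_per_trial
    first = int(np.ceil(discard_frac * n_trials))
    i0, i1 = int(trial_window[0] * spt), int(trial_window[1] * spt)
    if i1 <= i0:
        raise ValueError("empty trial window")
    r_out = result.r_out.reshape(n_trials, spt)[first:, i0:i1].mean(axis=1)
    s_bar = series.values.reshape(n_trials, spt)[first:, i0:i1].mean(axis=1)
    if against == "stimulus":
        x = s_bar
    elif against == "mu_in":
        x = series.trial_means[first:]
    else:
        raise ValueError(f"unknown regressor {against!r}")
    bias = r_out - s_bar
    if np.ptp(x) == 0:
        raise ValueError("degenerate trial stimuli; bias slope undefined")
    slope, intercept = np.polyfit(x, bias, 1)
    table = pd.DataFrame({"trial": np.arange(first, n_trials),
                          "trial_stimulus": x, "bias": bias})
    return BiasResult(table=table, slope=float(slope), intercept=float(intercept))


def bias_factor_sweeps(
    network: HierarchyNetwork,
    designs: dict[str, StimulusProtocol],
    seed: int = 0,
    discard_frac: float = 0.25,
) -> pd.DataFrame:
    """Bias slope per named protocol condition (independent seeded runs)."""
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(designs))
    for child, (name, proto) in zip(children, designs.items()):
        run_seed = int(child.generate_state(1)[0] % (2 ** 31))
        try:
            res = run_simulation(network, proto, seed=run_seed)
            br = compute_bias(res, discard_frac=discard_frac)
            rows.append(dict(condition=name, seed=run_seed,
                             slope=br.slope, magnitude=br.magnitude,
                             trial_duration_ms=proto.trial_duration_ms,
                             sigma2_in=proto.sigma2_in,
                             sigma2_trial=proto.sigma2_trial, error=""))
        except Exception as exc:
            log.error("condition %s failed: %s", name, exc)
            rows.append(dict(condition=name, seed=run_seed, slope=np.nan,
                             magnitude=np.nan,
                             trial_duration_ms=proto.trial_duration_ms,
                             sigma2_in=proto.sigma2_in,
                             sigma2_trial=proto.sigma2_trial, error=str(exc)))
    return pd.DataFrame(rows)
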