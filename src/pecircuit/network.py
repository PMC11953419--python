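"""The two-level hierarchy: PE circuits plus memory and variance neurons.

The lower circuit compares the external stimulus ``s`` with the lower memory
rate; its memory neuron is a perfect integrator of the gain-normalized PE
rates (weights ``lambda/g``), so in steady state it is the exponential moving
average of the stimulus with effective time constant ``tau_E / lambda``.  The
higher circuit receives the lower memory rate as its feedforward input and
forms a (slower) prediction of the prediction.  Each level's variance neuron
is a leaky integrator with quadratic activation of the summed, normalized PE
rates (tau_V = 5 s); its steady state estimates the variance of that level's
feedforward input.

The sensory weight ``alpha = (1 + r_V_low / r_V_high)^-1`` and the weighted
output ``r_out = alpha * s + (1 - alpha) * r_M_low`` are computed
arithmetically from the recorded rates; they do not feed back into the
dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .circuit import (
    PECircuitParams,
    PerturbationSpec,
    build_mfn,
    measure_gains,
)

__all__ = [
    "HierarchyNetwork",
    "NetworkState",
    "build_network",
    "step_network",
    "simulate_network",
    "sensory_weight",
    "weighted_output",
    "LAMBDA_LOW_DEFAULT",
    "LAMBDA_LOW_FIG2",
    "LAMBDA_HIGH_DEFAULT",
]

log = logging.getLogger(__name__)

# Non-normalized memory weights: the Fig. 2 single-level protocol uses the
# slower lower-level setting; the hierarchy experiments the faster one.
LAMBDA_LOW_FIG2 = 3e-3
LAMBDA_LOW_DEFAULT = 4.5e-2
LAMBDA_HIGH_DEFAULT = 7e-4
TAU_E_MS = 60.0
TAU_V_MS = 5000.0


@dataclass
class HierarchyNetwork:
    """Parameters of the composed lower + higher model."""

    lower: PECircuitParams
    higher: PECircuitParams
    lambda_low: float = LAMBDA_LOW_DEFAULT
    lambda_high: float = LAMBDA_HIGH_DEFAULT
    g_npe: float = 1.0
    g_ppe: float = 1.0
    tau_e: float = TAU_E_MS
    tau_v: float = TAU_V_MS

    def __post_init__(self) -> None:
        if min(self.lambda_low, self.lambda_high, self.g_npe, self.g_ppe,
               self.tau_e, self.tau_v) <= 0:
            raise ValueError("lambdas, gains and time constants must be positive")

    # Gain-normalized connection strengths (Methods-style: w = lambda / g
    # onto the memory neurons, w = 1 / g onto the variance neurons).
    @property
    def w_m_npe_low(self) -> float:
        return self.lambda_low / self.g_npe

    @property
    def w_m_ppe_low(self) -> float:
        return self.lambda_low / self.g_ppe

    @property
    def w_m_npe_high(self) -> float:
        return self.lambda_high / self.g_npe

    @property
    def w_m_ppe_high(self) -> float:
        return self.lambda_high / self.g_ppe

    @property
    def w_v_npe(self) -> float:
        return 1.0 / self.g_npe

    @property
    def w_v_ppe(self) -> float:
        return 1.0 / self.g_ppe

    @property
    def tau_m_low_eff(self) -> float:
        """Effective memory time constant of the lower level (ms)."""
        return self.tau_e / self.lambda_low

    @property
    def tau_m_high_eff(self) -> float:
        return self.tau_e / self.lambda_high

    @property
    def variant(self) -> str:
        return self.lower.variant


@dataclass
class NetworkState:
    """Full dynamical state: both circuit h-vectors plus M/V rates."""

    h_low: np.ndarray = field(default_factory=lambda: np.zeros(8))
    h_high: np.ndarray = field(default_factory=lambda: np.zeros(8))
    r_m_low: float = 0.0
    r_m_high: float = 0.0
    r_v_low: float = 0.0
    r_v_high: float = 0.0

    def __post_init__(self) -> None:
        if self.r_v_low < 0 or self.r_v_high < 0:
            raise ValueError("variance rates must be non-negative")


def build_network(
    variant: str = "MFN1",
    lambda_low: float = LAMBDA_LOW_DEFAULT,
    lambda_high: float = LAMBDA_HIGH_DEFAULT,
) -> HierarchyNetwork:
    """Build both subcircuits (identical, validated) and measure the PE gains.

    The two levels differ only in the effective memory timescale
    (``lambda_high < lambda_low`` makes the higher memory neuron slower).
    """
    params = build_mfn(variant)
    g_npe, g_ppe = measure_gains(params)
    return HierarchyNetwork(lower=params, higher=params,
                            lambda_low=lambda_low, lambda_high=lambda_high,
                            g_npe=g_npe, g_ppe=g_ppe)


def _pert_vectors(
    pert: PerturbationSpec | None,
) -> tuple[np.ndarray, np.ndarray]:
    if pert is None:
        z = np.zeros(8)
        return z, z
    v = pert.to_vector()
    z = np.zeros(8)
    lo = v if pert.scope in ("lower", "both") else z
    hi = v if pert.scope in ("higher", "both") else z
    return lo, hi


def simulate_network(
    net: HierarchyNetwork,
    stimulus: np.ndarray,
    pert: PerturbationSpec | None = None,
    onset_step: int | None = None,
    dt: float = 1.0,
    rates_stride: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Integrate the full system over a per-step stimulus from zero rates.

    Returns ``(summary, rates, counters)``: the per-step
    (r_M_low, r_V_low, r_M_high, r_V_high) array, the optionally strided
    16-channel circuit rates, and the numerical guard counters (variance
    floor clips, negative memory excursions).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    stim = np.ascontiguousarray(stimulus, dtype=np.float64)
    p_lo, p_hi = _pert_vectors(pert)
    if onset_step is None:
        onset_step = 0 if pert is not None else np.iinfo(np.int64).max
    summary, rates, counters = _kernels.simulate_hierarchy(
        net.lower.W, net.lower.w_ff, net.lower.w_fb, net.lower.I_bg,
        net.lower.tau, stim, float(dt),
        net.w_m_npe_low, net.w_m_ppe_low, net.w_m_npe_high, net.w_m_ppe_high,
        net.w_v_npe, net.w_v_ppe, net.tau_e, net.tau_v,
        p_lo, p_hi, int(onset_step), int(rates_stride),
    )
    if not np.all(np.isfinite(summary[-1])):
        raise FloatingPointError("network simulation diverged (NaN/Inf)")
    c = {"v_floor_clips": int(counters[0]), "m_negative_steps": int(counters[1])}
    if c["v_floor_clips"]:
        log.debug("variance floor engaged on %d stage updates", c["v_floor_clips"])
    if c["m_negative_steps"]:
        # brief negative excursions occur when the memory rate hovers near
        # zero (start-up, near-zero stimuli); sustained ones deserve a look
        level = (logging.WARNING
                 if c["m_negative_steps"] > 0.01 * stim.size else logging.DEBUG)
        log.log(level, "memory rate went negative on %d of %d steps",
                c["m_negative_steps"], stim.size)
    return summary, rates, c


def step_network(
    state: NetworkState,
    net: HierarchyNetwork,
    s: float,
    pert: PerturbationSpec | None = None,
    dt: float = 1.0,
) -> NetworkState:
    """Single Heun step of the coupled system, carrying explicit state.

    Semantically identical to one iteration of :func:`simulate_network`'s
    compiled loop; useful for stepping through short custom schedules and for
    convergence tests.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p_lo, p_hi = _pert_vectors(pert)
    prm = net.lower

    def rhs(h_lo, h_hi, m_lo, m_hi, v_lo, v_hi):
        r_lo = np.maximum(h_lo, 0.0)
        r_hi = np.maximum(h_hi, 0.0)
        d_lo = (-h_lo + prm.W @ r_lo + prm.w_ff * s + prm.w_fb * m_lo
                + prm.I_bg + p_lo) / prm.tau
        d_hi = (-h_hi + prm.W @ r_hi + prm.w_ff * m_lo + prm.w_fb * m_hi
                + prm.I_bg + p_hi) / prm.tau
        d_ml = (net.w_m_ppe_low * r_lo[1] - net.w_m_npe_low * r_lo[0]) / net.tau_e
        d_mh = (net.w_m_ppe_high * r_hi[1] - net.w_m_npe_high * r_hi[0]) / net.tau_e
        pe_lo = net.w_v_ppe * r_lo[1] + net.w_v_npe * r_lo[0]
        pe_hi = net.w_v_ppe * r_hi[1] + net.w_v_npe * r_hi[0]
        d_vl = (-v_lo + pe_lo ** 2) / net.tau_v
        d_vh = (-v_hi + pe_hi ** 2) / net.tau_v
        return d_lo, d_hi, d_ml, d_mh, d_vl, d_vh

    y = (state.h_low, state.h_high, state.r_m_low, state.r_m_high,
         state.r_v_low, state.r_v_high)
    k1 = rhs(*y)
    y2 = tuple(a + dt * b for a, b in zip(y, k1))
    k2 = rhs(*y2)
    out = tuple(a + 0.5 * dt * (b + c) for a, b, c in zip(y, k1, k2))
    if not (np.all(np.isfinite(out[0])) and np.all(np.isfinite(out[1]))
            and all(np.isfinite(x) for x in out[2:])):
        raise FloatingPointError("network state diverged (NaN/Inf)")
    return NetworkState(h_low=out[0], h_high=out[1],
                        r_m_low=out[2], r_m_high=out[3],
                        r_v_low=max(out[4], 0.0), r_v_high=max(out[5], 0.0))


def sensory_weight(r_v_low, r_v_high):
    """Sensory weight alpha = (1 + r_V_low / r_V_high)^-1, elementwise.

    Zero-variance limits: both variances zero means the network represents
    the sensory input perfectly (alpha = 1); a zero higher variance with a
    positive lower variance means full reliance on the prediction (alpha = 0).
    """
    vl = np.asarray(r_v_low, float)
    vh = np.asarray(r_v_high, float)
    if np.any(vl < 0) or np.any(vh < 0):
        raise ValueError("variance rates must be non-negative")
    total = vl + vh
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(total > 0, vh / np.where(total > 0, total, 1.0), 1.0)
    if alpha.ndim == 0:
        return float(alpha)
    return alpha


def weighted_output(s, r_m_low, alpha):
    """Convex combination r_out = alpha * s + (1 - alpha) * r_M_low."""
    a = np.asarray(alpha, float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("alpha must lie in [0, 1]")
    out = a * np.asarray(s, float) + (1.0 - a) * np.asarray(r_m_low, float)
    if out.ndim == 0:
        return float(out)
    return out
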