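"""Numba-compiled inner loops for the hierarchical network simulation.

The full model is a 20-dimensional ODE system (two 8-unit circuits plus two
memory and two variance rates) integrated with a fixed-step second-order
Runge-Kutta (Heun) scheme at millisecond resolution; runs span 10^5-10^6
steps, so the loop is JIT-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_hierarchy(
    W: np.ndarray,            # (8, 8)
    w_ff: np.ndarray,         # (8,)
    w_fb: np.ndarray,         # (8,)
    I_bg: np.ndarray,         # (8,)
    tau: np.ndarray,          # (8,)
    stim: np.ndarray,         # (n,) per-step stimulus
    dt: float,
    w_m_npe_low: float, w_m_ppe_low: float,
    w_m_npe_high: float, w_m_ppe_high: float,
    w_v_npe: float, w_v_ppe: float,
    tau_e: float, tau_v: float,
    pert_low: np.ndarray,     # (8,)
    pert_high: np.ndarray,    # (8,)
    onset_step: int,
    rates_stride: int,        # 0 disables rate recording
):
    """Integrate the coupled two-level system from zero initial rates.

    Returns ``(summary, rates, counters)`` where ``summary`` is an (n, 4)
    array of (r_M_low, r_V_low, r_M_high, r_V_high) after each step,
    ``rates`` an (n // stride, 16) array of the circuit rates (empty if
    stride is 0) and ``counters`` the number of variance-floor clips and
    negative-memory guard events.
    """
    n = stim.shape[0]
    h_lo = np.zeros(8)
    h_hi = np.zeros(8)
    r_m_lo = 0.0
    r_m_hi = 0.0
    r_v_lo = 0.0
    r_v_hi = 0.0
    summary = np.empty((n, 4))
    n_rec = n // rates_stride if rates_stride > 0 else 0
    rates = np.empty((n_rec, 16))
    zero8 = np.zeros(8)
    n_v_clip = 0
    n_m_neg = 0

    for t in range(n):
        s = stim[t]
        if t >= onset_step:
            p_lo = pert_low
            p_hi = pert_high
        else:
            p_lo = zero8
            p_hi = zero8

        # stage 1
        r_lo = np.maximum(h_lo, 0.0)
        r_hi = np.maximum(h_hi, 0.0)
        k1_lo = (-h_lo + W @ r_lo + w_ff * s + w_fb * r_m_lo + I_bg + p_lo) / tau
        k1_hi = (-h_hi + W @ r_hi + w_ff * r_m_lo + w_fb * r_m_hi + I_bg + p_hi) / tau
        k1_ml = (w_m_ppe_low * r_lo[1] - w_m_npe_low * r_lo[0]) / tau_e
        k1_mh = (w_m_ppe_high * r_hi[1] - w_m_npe_high * r_hi[0]) / tau_e
        pe_lo = w_v_ppe * r_lo[1] + w_v_npe * r_lo[0]
        pe_hi = w_v_ppe * r_hi[1] + w_v_npe * r_hi[0]
        k1_vl = (-r_v_lo + pe_lo * pe_lo) / tau_v
        k1_vh = (-r_v_hi + pe_hi * pe_hi) / tau_v

        # stage 2 (full Euler predictor)
        h_lo2 = h_lo + dt * k1_lo
        h_hi2 = h_hi + dt * k1_hi
        m_lo2 = r_m_lo + dt * k1_ml
        m_hi2 = r_m_hi + dt * k1_mh
        v_lo2 = r_v_lo + dt * k1_vl
        v_hi2 = r_v_hi + dt * k1_vh
        r_lo2 = np.maximum(h_lo2, 0.0)
        r_hi2 = np.maximum(h_hi2, 0.0)
        k2_lo = (-h_lo2 + W @ r_lo2 + w_ff * s + w_fb * m_lo2 + I_bg + p_lo) / tau
        k2_hi = (-h_hi2 + W @ r_hi2 + w_ff * m_lo2 + w_fb * m_hi2 + I_bg + p_hi) / tau
        k2_ml = (w_m_ppe_low * r_lo2[1] - w_m_npe_low * r_lo2[0]) / tau_e
        k2_mh = (w_m_ppe_high * r_hi2[1] - w_m_npe_high * r_hi2[0]) / tau_e
        pe_lo2 = w_v_ppe * r_lo2[1] + w_v_npe * r_lo2[0]
        pe_hi2 = w_v_ppe * r_hi2[1] + w_v_npe * r_hi2[0]
        k2_vl = (-v_lo2 + pe_lo2 * pe_lo2) / tau_v
        k2_vh = (-v_hi2 + pe_hi2 * pe_hi2) / tau_v

        h_lo = h_lo + 0.5 * dt * (k1_lo + k2_lo)
        h_hi = h_hi + 0.5 * dt * (k1_hi + k2_hi)
        r_m_lo = r_m_lo + 0.5 * dt * (k1_ml + k2_ml)
        r_m_hi = r_m_hi + 0.5 * dt * (k1_mh + k2_mh)
        r_v_lo = r_v_lo + 0.5 * dt * (k1_vl + k2_vl)
        r_v_hi = r_v_hi + 0.5 * dt * (k1_vh + k2_vh)
        if r_v_lo < 0.0:
            r_v_lo = 0.0
            n_v_clip += 1
        if r_v_hi < 0.0:
            r_v_hi = 0.0
            n_v_clip += 1
        if r_m_lo < 0.0 or r_m_hi < 0.0:
            n_m_neg += 1

        summary[t, 0] = r_m_lo
        summary[t, 1] = r_v_lo
        summary[t, 2] = r_m_hi
        summary[t, 3] = r_v_hi
        if rates_stride > 0 and t % rates_stride == 0:
            idx = t // rates_stride
            if idx < n_rec:
                for j in range(8):
                    rates[idx, j] = max(h_lo[j], 0.0)
                    rates[idx, 8 + j] = max(h_hi[j], 0.0)

    counters = np.array([n_v_clip, n_m_neg], dtype=np.int64)
    return summary, rates, counters
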