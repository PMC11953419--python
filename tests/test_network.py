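"""The two-level hierarchy: weighting formulas, oracles, composition."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pecircuit as pc
from pecircuit.circuit import replace_bg
from pecircuit.idealized import ema_closed_form
from pecircuit.network import (
    NetworkState,
    sensory_weight,
    simulate_network,
    step_network,
    weighted_output,
)


@pytest.mark.parametrize("vl, vh, expected", [
    (1.0, 1.0, 0.5),
    (0.0, 2.5, 1.0),     # noise-free stimulus: rely fully on the senses
    (3.0, 1.0, 0.25),
    (0.0, 0.0, 1.0),     # both variances zero: input represented perfectly
    (2.0, 0.0, 0.0),     # perfectly certain prediction
])
def test_sensory_weight_values_and_limits(vl, vh, expected):
    assert sensory_weight(vl, vh) == pytest.approx(expected)


def test_sensory_weight_rejects_negative():
    with pytest.raises(ValueError):
        sensory_weight(-1.0, 1.0)


@given(vl=st.floats(0, 1e9), vh=st.floats(0, 1e9))
def test_sensory_weight_bounded(vl, vh):
    a = sensory_weight(vl, vh)
    assert 0.0 <= a <= 1.0
    if vl == vh and vl > 0:
        assert a == pytest.approx(0.5)


@pytest.mark.parametrize("alpha, s, r_m, expected", [
    (1.0, 4.0, 8.0, 4.0),
    (0.0, 4.0, 8.0, 8.0),
    (0.25, 4.0, 8.0, 7.0),
])
def test_weighted_output_values(alpha, s, r_m, expected):
    assert weighted_output(s, r_m, alpha) == pytest.approx(expected)


def test_weighted_output_rejects_bad_alpha():
    with pytest.raises(ValueError):
        weighted_output(1.0, 2.0, 1.5)
    with pytest.raises(ValueError):
        weighted_output(1.0, 2.0, -0.1)


@given(alpha=st.floats(0, 1), s=st.floats(-100, 100), r_m=st.floats(-100, 100))
def test_weighted_output_convexity(alpha, s, r_m):
    out = weighted_output(s, r_m, alpha)
    assert min(s, r_m) - 1e-9 <= out <= max(s, r_m) + 1e-9


def test_build_network_defaults_and_derived_weights(net_mfn1):
    net = net_mfn1
    assert net.lambda_low == pytest.approx(4.5e-2)
    assert net.lambda_high == pytest.approx(7e-4)
    assert net.w_v_npe == pytest.approx(1.0 / net.g_npe)
    assert net.w_m_npe_low == pytest.approx(net.lambda_low / net.g_npe)
    # the higher memory neuron is slower by exactly the lambda ratio
    assert net.tau_m_high_eff / net.tau_m_low_eff == pytest.approx(
        net.lambda_low / net.lambda_high)
    assert net.tau_m_low_eff == pytest.approx(60.0 / 4.5e-2)


def test_fig2_lambda_preset():
    net = pc.build_network("MFN1", lambda_low=pc.LAMBDA_LOW_FIG2)
    assert net.tau_m_low_eff == pytest.approx(20000.0)


def test_constant_stimulus_fixed_point(net_mfn1):
    """Constant input: memory converges to it, PE and variance rates vanish."""
    stim = np.full(30000, 4.0)
    summary, rates, _ = simulate_network(net_mfn1, stim, rates_stride=100)
    assert summary[-1, 0] == pytest.approx(4.0, abs=0.01)     # r_M_low -> s
    assert summary[-1, 1] == pytest.approx(0.0, abs=0.01)     # r_V_low -> 0
    assert rates[-1, 0] < 1e-3 and rates[-1, 1] < 1e-3        # PE silent
    assert summary[0, 0] < 0.02                               # zero init


def test_memory_neuron_matches_ema_oracle(net_mfn1):
    """The circuit memory neuron follows the closed-form exponential moving
    average with tau = tau_E / lambda on a random piecewise-constant input.

    The residual reflects the PE neurons' own 60-ms response time and the
    nonlinear over-response to the large start-up mismatches; both are small
    against the stimulus range.
    """
    rng = np.random.default_rng(42)
    segs = [(float(rng.uniform(2, 8)), float(rng.integers(200, 500)))
            for _ in range(10)]
    stim = np.concatenate([np.full(int(T), c) for c, T in segs])
    summary, _, _ = simulate_network(net_mfn1, stim)
    oracle = ema_closed_form(segs, net.tau_m_low_eff if (net := net_mfn1) else 0)
    ends = np.cumsum([int(T) for _, T in segs]) - 1
    err = np.abs(summary[ends, 0] - oracle)
    assert err.max() < 0.06 * np.ptp(stim)


def test_step_network_agrees_with_kernel(net_mfn1):
    stim = np.linspace(2.0, 6.0, 200)
    summary, _, _ = simulate_network(net_mfn1, stim)
    state = NetworkState()
    for s in stim:
        state = step_network(state, net_mfn1, float(s))
    assert state.r_m_low == pytest.approx(summary[-1, 0], abs=1e-10)
    assert state.r_v_low == pytest.approx(summary[-1, 1], abs=1e-10)
    assert state.r_v_high == pytest.approx(summary[-1, 3], abs=1e-10)


def test_step_network_rejects_bad_dt(net_mfn1):
    with pytest.raises(ValueError):
        step_network(NetworkState(), net_mfn1, 1.0, dt=-1.0)


def test_equal_pe_baseline_offsets(net_mfn1):
    """Equal PE baseline offsets leave the mean estimate unchanged but
    inflate the variance estimate."""
    proto = pc.get_preset("fig3D", n_trials=20)
    series = pc.render_protocol(proto, seed=9)
    base, _, _ = simulate_network(net_mfn1, series.values)

    off = net_mfn1.lower.I_bg.copy()
    off[0] += 0.3
    off[1] += 0.3
    shifted_params = replace_bg(net_mfn1.lower, off)
    shifted = pc.HierarchyNetwork(
        lower=shifted_params, higher=shifted_params,
        lambda_low=net_mfn1.lambda_low, lambda_high=net_mfn1.lambda_high,
        g_npe=net_mfn1.g_npe, g_ppe=net_mfn1.g_ppe)
    mod, _, _ = simulate_network(shifted, series.values)

    half = base.shape[0] // 2
    dm = abs(mod[half:, 0].mean() - base[half:, 0].mean())
    assert dm < 0.05                                   # mean unchanged
    assert mod[half:, 1].mean() > base[half:, 1].mean() * 1.1   # variance up


def test_joint_lambda_scaling_is_weak(net_mfn1):
    """Scaling both memory weights together barely moves the sensory weight,
    while scaling only the lower one moves it strongly."""
    proto = pc.get_preset("fig3E", n_trials=50)
    series = pc.render_protocol(proto, seed=4)

    def alpha_for(lam_low, lam_high):
        net = pc.HierarchyNetwork(
            lower=net_mfn1.lower, higher=net_mfn1.higher,
            lambda_low=lam_low, lambda_high=lam_high,
            g_npe=net_mfn1.g_npe, g_ppe=net_mfn1.g_ppe)
        summary, _, _ = simulate_network(net, series.values)
        half = summary.shape[0] // 2
        return sensory_weight(summary[half:, 1].mean(), summary[half:, 3].mean())

    a0 = alpha_for(4.5e-2, 7e-4)
    for factor in (2.0, 10.0):
        a_joint = alpha_for(4.5e-2 * factor, 7e-4 * factor)
        a_asym = alpha_for(4.5e-2 * factor, 7e-4)
        assert abs(a_joint - a0) < abs(a_asym - a0)


def test_network_divergence_raises(net_mfn1):
    with pytest.raises(FloatingPointError):
        simulate_network(net_mfn1, np.full(50, 1e300))
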