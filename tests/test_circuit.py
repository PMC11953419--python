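"""The eight-unit microcircuit: balance, calibration, responses, perturbations."""

import numpy as np
import pytest

import pecircuit as pc
from pecircuit.circuit import (
    DEFAULT_BASELINES,
    CircuitState,
    PECircuitParams,
    PerturbationSpec,
    calibrate_background,
    fit_baseline_gain,
    replace_bg,
    simulate_circuit,
    step_circuit,
    verify_pe_responses,
)

VARIANTS = ("MFN1", "MFN2", "MFN3")


@pytest.mark.parametrize("variant", VARIANTS)
def test_structure_invariants(mfn_params, variant):
    p = mfn_params[variant]
    p.validate_structure()   # Dale signs, routing, compartment targeting
    assert np.allclose(p.w_ff + p.w_fb, 1.0)
    # dendrites and PV2 receive the prediction; somata and PV1 the stimulus
    assert np.all(p.w_fb[[2, 3, 5]] == 1.0)
    assert np.all(p.w_ff[[0, 1, 4]] == 1.0)
    som_fb = {"MFN1": 0.0, "MFN2": 1.0, "MFN3": 0.0}[variant]
    vip_fb = {"MFN1": 1.0, "MFN2": 0.0, "MFN3": 0.0}[variant]
    assert p.w_fb[6] == som_fb and p.w_fb[7] == vip_fb
    # SOM <-> VIP mutual inhibition and SOM/VIP -> PV present
    assert p.W[6, 7] < 0 and p.W[7, 6] < 0
    assert np.all(p.W[4:6, 6:8] < 0)


@pytest.mark.parametrize("variant", VARIANTS)
def test_baseline_calibration(mfn_params, variant):
    r = simulate_circuit(mfn_params[variant], 0.0, 0.0, duration_ms=3000.0)
    assert np.max(np.abs(r - DEFAULT_BASELINES)) < 0.01


@pytest.mark.parametrize("variant", VARIANTS)
def test_pe_response_pattern(mfn_params, variant):
    rep = verify_pe_responses(mfn_params[variant])
    assert rep.passed, rep.failures
    assert rep.gain_npe > 0 and rep.gain_ppe > 0
    for mm, (rn, rp) in rep.responses.items():
        assert min(rn, rp) <= 1e-3          # complementarity at steady state


@pytest.mark.parametrize("variant", VARIANTS)
def test_ei_balance_common_input_invariance(mfn_params, variant):
    """Raising stimulus and prediction together leaves PE somata at baseline."""
    p = mfn_params[variant]
    for x in (2.0, 8.0):
        r = simulate_circuit(p, x, x, duration_ms=3000.0)
        assert r[0] < 1e-3 and r[1] < 1e-3


def test_calibration_decoupled_and_idempotent(mfn1):
    # zero connectivity: background equals the target rates exactly
    free = PECircuitParams(W=np.zeros((8, 8)), w_ff=mfn1.w_ff.copy(),
                           w_fb=mfn1.w_fb.copy(), I_bg=np.zeros(8),
                           variant=mfn1.variant)
    I = calibrate_background(free, check=False)
    assert np.array_equal(I, DEFAULT_BASELINES)
    # recalibrating a calibrated circuit returns the same inputs
    I2 = calibrate_background(mfn1)
    assert np.allclose(I2, mfn1.I_bg)


def test_decoupled_excitatory_unit_relaxes_with_tau_e():
    """An isolated excitatory unit approaches a step input with tau = 60 ms."""
    p = PECircuitParams(W=np.zeros((8, 8)), w_ff=np.ones(8), w_fb=np.zeros(8),
                        I_bg=np.zeros(8))
    st = CircuitState.zeros()
    for _ in range(60):
        st = step_circuit(st, p, ff=1.0, fb=0.0, dt=1.0)
    assert st.r[0] == pytest.approx(1.0 - np.exp(-1.0), abs=0.01)


def test_step_circuit_errors(mfn1):
    with pytest.raises(ValueError):
        step_circuit(CircuitState.zeros(), mfn1, 0.0, 0.0, dt=0.0)
    with pytest.raises(FloatingPointError):
        step_circuit(CircuitState(h=np.full(8, np.nan)), mfn1, 1.0, 0.0, dt=1.0)


def test_rk2_self_convergence(mfn1):
    """Trajectory error shrinks ~16x per fourfold dt refinement."""
    def endpoint(dt):
        st = CircuitState.zeros()
        for _ in range(int(400 / dt)):
            st = step_circuit(st, mfn1, 6.0, 5.0, None, dt)
        return st.r

    ref = endpoint(0.0625)
    e1 = np.abs(endpoint(1.0) - ref).max()
    e2 = np.abs(endpoint(0.25) - ref).max()
    assert e1 / e2 == pytest.approx(16.0, rel=0.6)


def test_serialization_round_trip(mfn1, tmp_path):
    path = tmp_path / "mfn1.json"
    mfn1.to_json(path)
    back = PECircuitParams.from_json(path)
    assert np.allclose(back.W, mfn1.W)
    assert np.allclose(back.I_bg, mfn1.I_bg)
    assert back.variant == mfn1.variant
    # an externally supplied matrix loads verbatim and re-validates
    rep = verify_pe_responses(back)
    assert rep.passed


def test_fit_baseline_gain_unperturbed(mfn1):
    """Without modulation the fitted baselines are zero and the slopes match
    the two-point response gains."""
    fits = fit_baseline_gain(mfn1)
    g_n, g_p = pc.measure_gains(mfn1)
    assert fits["nPE"].intercept == pytest.approx(0.0, abs=0.02)
    assert fits["pPE"].intercept == pytest.approx(0.0, abs=0.02)
    assert fits["nPE"].slope == pytest.approx(g_n, rel=0.05)
    assert fits["pPE"].slope == pytest.approx(g_p, rel=0.05)


@pytest.mark.parametrize("variant", VARIANTS)
def test_pv_activation_lowers_baseline_and_gain(mfn_params, variant):
    """Extra PV drive shifts both PE response curves down and shallower."""
    p = mfn_params[variant]
    base = fit_baseline_gain(p)
    pert = PerturbationSpec(targets={"PV": 1.0})
    mod = fit_baseline_gain(p, pert=pert.to_vector())
    for neuron in ("nPE", "pPE"):
        assert mod[neuron].intercept < base[neuron].intercept + 1e-6
        assert mod[neuron].slope < base[neuron].slope - 1e-3


def test_perturbation_spec_validation():
    with pytest.raises(ValueError):
        PerturbationSpec(targets={"PV": -0.5})
    with pytest.raises(ValueError):
        PerturbationSpec(targets={"AMPA": 0.5})
    with pytest.raises(ValueError):
        PerturbationSpec(targets={"PV": 0.5}, scope="everywhere")
    v = PerturbationSpec(targets={"PV": 0.5, "SOM": 0.2}).to_vector()
    assert np.array_equal(v, [0, 0, 0, 0, 0.5, 0.5, 0.2, 0])


def test_build_rejects_unknown_variant():
    with pytest.raises(ValueError):
        pc.build_mfn("MFN4")


def test_common_baseline_offset_preserves_complementary_sum(mfn1):
    """Equal background offsets to both somata raise both PE baselines alike."""
    off = mfn1.I_bg.copy()
    off[0] += 0.3
    off[1] += 0.3
    shifted = replace_bg(mfn1, off)
    r = simulate_circuit(shifted, 5.0, 5.0, duration_ms=3000.0)
    assert r[0] > 0.05 and r[1] > 0.05
    assert r[0] == pytest.approx(r[1], rel=0.05)
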