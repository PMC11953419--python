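"""Experiment drivers: weighting regimes, perturbations, contraction bias."""

import numpy as np
import pandas as pd
import pytest

import pecircuit as pc
from pecircuit.experiments import (
    SimulationResult,
    compute_bias,
    steady_state_alpha,
    time_resolved_alpha,
)
from pecircuit.stimuli import StimulusProtocol, StimulusSeries


def _synthetic_result(alpha, n_trials=40, n_values=5, spv=10, seed=0,
                      sigma2_in=0.0):
    """A SimulationResult whose weighted output follows the closed-form
    r_out = alpha * s + (1 - alpha) * mu_bar with converged prediction."""
    proto = StimulusProtocol(n_trials, n_values, spv, (10.0, 20.0),
                             sigma2_in=sigma2_in)
    series = pc.render_protocol(proto, seed=seed)
    mu_bar = series.trial_means.mean()
    n = series.values.size
    r_out = alpha * series.values + (1 - alpha) * mu_bar
    summary = np.zeros((n, 4))
    return SimulationResult(
        stimulus=series, summary=summary, alpha=np.full(n, alpha),
        r_out=r_out, protocol=proto, seed=seed, variant="MFN1",
        lambda_low=1.0, lambda_high=1.0)


@pytest.mark.parametrize("alpha", [0.0, 0.3, 0.75, 1.0])
def test_compute_bias_closed_form_oracle(alpha):
    """With r_out = alpha*s + (1-alpha)*mu_bar the bias-vs-stimulus slope is
    exactly -(1 - alpha): full reliance on the senses gives no bias, full
    reliance on the converged prediction gives slope -1."""
    br = compute_bias(_synthetic_result(alpha))
    assert br.slope == pytest.approx(-(1.0 - alpha), abs=1e-9)
    assert br.magnitude == pytest.approx(1.0 - alpha, abs=1e-9)


def test_compute_bias_sign_pattern():
    br = compute_bias(_synthetic_result(0.4))
    mu_bar = 15.0
    below = br.table[br.table.trial_stimulus < mu_bar - 0.5].bias
    above = br.table[br.table.trial_stimulus > mu_bar + 0.5].bias
    assert (below > 0).all() and (above < 0).all()


def test_compute_bias_degenerate_regressor_raises(net_mfn1):
    proto = StimulusProtocol(8, 2, 5, 5.0, sigma2_in=0.0)
    res = pc.run_simulation(net_mfn1, proto, seed=0)
    with pytest.raises(ValueError):
        compute_bias(res)


def test_compute_bias_mu_in_regressor():
    br = compute_bias(_synthetic_result(0.5), against="mu_in")
    assert br.slope == pytest.approx(-0.5, abs=0.02)
    with pytest.raises(ValueError):
        compute_bias(_synthetic_result(0.5), against="median")


def test_zero_stimulus_stays_at_fixed_point(net_mfn1):
    proto = StimulusProtocol(2, 5, 400, 0.0, sigma2_in=0.0)
    res = pc.run_simulation(net_mfn1, proto, seed=0, rates_stride=50)
    assert np.abs(res.r_m_low).max() < 1e-6
    # after the start-up transient (the interneurons begin at rest, not at
    # their baseline) the PE somata are silent and the interneurons hold 4/s
    settled = res.rates[20:]
    assert settled[:, 0].max() < 1e-3 and settled[:, 1].max() < 1e-3
    assert np.abs(settled[:, 4:8] - 4.0).max() < 0.01


def test_steady_state_alpha_methods(net_mfn1):
    res = pc.run_simulation(net_mfn1, pc.get_preset("fig3D", n_trials=30), seed=1)
    a_ratio = steady_state_alpha(res)
    a_mean = steady_state_alpha(res, method="mean_alpha")
    for a in (a_ratio, a_mean):
        assert 0.0 < a < 0.5          # prediction-dominated regime
    with pytest.raises(ValueError):
        steady_state_alpha(res, method="harmonic")


def test_limit_case_regimes(net_mfn1):
    """Noise-free volatile stimuli are sensory-dominated; noisy stable
    stimuli are prediction-dominated."""
    a_c = steady_state_alpha(pc.run_simulation(
        net_mfn1, pc.get_preset("fig3C", n_trials=60), seed=2))
    a_d = steady_state_alpha(pc.run_simulation(
        net_mfn1, pc.get_preset("fig3D", n_trials=60), seed=2))
    assert a_c > 0.5
    assert a_d < 0.5


def test_time_resolved_alpha_onset_dip_and_control(net_mfn1):
    """A change point drags the sensory weight down with the variance
    integrator's lag; without change points the profile is flat."""
    res = pc.run_simulation(net_mfn1, pc.get_preset("fig3F_5s", n_trials=40),
                            seed=3)
    prof = time_resolved_alpha(res).alpha_mean.values
    start = prof[: len(prof) // 20].mean()
    assert prof.min() < start - 0.01
    assert np.argmin(prof) > len(prof) // 20

    control = StimulusProtocol(100, 10, 500, 5.0, sigma2_in=5.0)
    res_c = pc.run_simulation(net_mfn1, control, seed=3)
    prof_c = time_resolved_alpha(res_c).alpha_mean.values
    # without change points the profile is flat (apart from the slow global
    # convergence trend and Monte-Carlo residue), far below the dip depth
    trend = np.polyval(np.polyfit(np.arange(prof_c.size), prof_c, 1),
                       np.arange(prof_c.size))
    assert np.ptp(prof_c - trend) < 0.012
    assert np.ptp(prof_c - trend) < 0.5 * (start - prof.min())


def test_time_resolved_alpha_needs_trials(net_mfn1):
    res = pc.run_simulation(net_mfn1, pc.get_preset("fig3D", n_trials=12), seed=0)
    with pytest.raises(ValueError):
        time_resolved_alpha(res, discard_frac=0.9)


def test_variance_grid_sweep_shape_and_failure_manifest(net_mfn1):
    df = pc.sweep_variance_grid(net_mfn1, [0.0, 5.0], [0.0, 5.0],
                                n_trials=10, seed=0)
    assert len(df) == 4
    assert set(df.columns) >= {"sigma2_in", "sigma2_trial", "alpha", "error"}
    assert (df.error == "").all()
    # the double-zero cell is the perfect-representation limit
    cell = df[(df.sigma2_in == 0) & (df.sigma2_trial == 0)]
    assert cell.alpha.iloc[0] == pytest.approx(1.0, abs=1e-2)


def test_perturbation_experiment_validation(net_mfn1):
    with pytest.raises(ValueError):
        pc.perturbation_experiment(net_mfn1, "twilight")
    with pytest.raises(ValueError):
        pc.perturbation_experiment(net_mfn1, "sensory",
                                   target_sets=[("GABA-B",)])


def test_perturbation_experiment_table(net_mfn1):
    df = pc.perturbation_experiment(
        net_mfn1, "prediction", target_sets=[("PV",)],
        strengths=(0.0, 1.0), n_trials=30, seed=5)
    assert list(df.strength) == [0.0, 1.0]
    assert df.delta_alpha.iloc[0] == 0.0    # strength zero is the reference
    assert df.v_signal_frac.iloc[0] == 1.0
    # strong PV drive suppresses the variance signal
    assert df.v_signal_frac.iloc[1] < 0.5


def test_bias_factor_sweeps_reports_conditions(net_mfn1):
    designs = {
        "short": pc.get_preset("fig5C_narrow", n_trials=40),
        "long": pc.get_preset("fig5C_narrow", n_trials=40,
                              steps_per_value=1000),
    }
    df = pc.bias_factor_sweeps(net_mfn1, designs, seed=2)
    assert set(df.condition) == {"short", "long"}
    assert (df.error == "").all()
    short = df[df.condition == "short"].magnitude.iloc[0]
    long = df[df.condition == "long"].magnitude.iloc[0]
    assert long < short                     # longer trials reduce the bias
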