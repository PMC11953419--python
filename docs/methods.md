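# Methods

## Model equations

Each of the two hierarchical levels contains one prediction-error (PE)
microcircuit, one memory neuron and one variance neuron.

**PE circuit.** Eight units in fixed order — nE, pE (PE-neuron somata), nD,
pD (their dendritic compartments), PV1, PV2, SOM, VIP — with rectified
linear dynamics

    T_c dh/dt = -h + W r + w_fb * p + w_ff * s + I_bg,   r = [h]_+ .

`T_c` is diagonal with tau_E = 60 ms for the four excitatory entries
(somata and dendrites) and tau_I = 2 ms for the interneurons.  Routing is
complementary, `w_ff = 1 - w_fb`, with the somata and PV1 always
stimulus-targeted and the dendrites and PV2 always prediction-targeted.
The three wirings differ only in the SOM/VIP routing: MFN1 (default) gives
SOM the stimulus and VIP the prediction, MFN2 swaps them, MFN3 gives both
the stimulus.  Rectification applies to every entry, dendrites included, at
both stages of every integration step.

**Memory neuron.** A perfect integrator of the gain-normalized PE rates,

    tau_E dr_M/dt = (lambda / g_pPE) r_pE - (lambda / g_nPE) r_nE ,

where `g_nPE`, `g_pPE` are the measured steady-state response gains of the
circuit.  Because the normalization cancels the gains, the drive is
`lambda * (s - r_M)` and the memory rate is the exponential moving average
of the level's feedforward input with effective time constant
`tau_M = tau_E / lambda`.  Note this differs from the superficially
plausible `tau_E * g / lambda`: with `w = lambda / g` and `r = g * |s - p|`
the gain cancels.  The defaults are lambda_low = 4.5e-2 (tau_M = 1.33 s;
the single-level estimation protocol instead uses 3e-3, tau_M = 20 s) and
lambda_high = 7e-4 (tau_M = 85.7 s); the lower/higher timescale ratio is
therefore exactly lambda_low / lambda_high.

**Variance neuron.** A leaky integrator with quadratic activation,

    tau_V dr_V/dt = -r_V + (r_pE / g_pPE + r_nE / g_nPE)^2 ,   tau_V = 5 s,

whose steady state estimates the variance of the level's feedforward input.

**Weighted output.** Computed arithmetically, not fed back:
`alpha = r_V_high / (r_V_low + r_V_high)`,
`r_out = alpha * s + (1 - alpha) * r_M_low`.  Zero-variance limits: both
variances zero gives alpha = 1 (perfect representation of the input); a
zero higher variance with positive lower variance gives alpha = 0.

## The connectivity solve

The intra-circuit weight magnitudes are derived, not fitted.  The sign and
routing template is fixed (Dale's law; PV onto somata; SOM onto dendrites;
SOM–VIP mutual inhibition 0.5; SOM/VIP onto PV 0.05); the remaining
magnitudes follow from three constraints, writing (c_s, c_p) for a unit's
steady-state input coefficients with respect to stimulus and prediction:

1. *Predicted-input balance.*  The interneuron block is autonomous and
   linear while the PE somata are silent, so its response slopes to (s, p)
   are known in closed form.  The two PV weights onto each soma are solved
   from a 2x2 system that pins the soma's total coefficients — direct
   stimulus, dendritic drive, PV inhibition — to (-gamma, +gamma) for nE
   and (+gamma, -gamma) for pE.  Fully predicted inputs then cancel exactly
   at any input level (the input-balance invariance), mismatch responses
   are one-sided and linear with gain gamma, and the nE/pE gammas are kept
   equal so equal baseline offsets in the two PE neurons cancel exactly in
   the memory drive.
2. *Dendritic operating point.*  The SOM weight onto each dendrite is kept
   below the predicted-manifold drive, so the dendrites are active (above
   threshold) during stimulation and the dendro-somatic pathway stays in
   the linear range where constraint 1 can cancel it.
3. *Neuromodulation neutrality.*  Equal extra drive onto SOM and VIP raises
   both their rates by delta / (1 + w_SOM-VIP); the resulting somatic
   disinhibition through the SOM/VIP->PV pathway must equal the extra
   dendritic inhibition transmitted to the soma.  This pins the
   dendro-somatic coupling in closed form:
   `w_soma<-dend * w_dend<-SOM = 2 * w_PV<-SOM * (sum of the soma's PV
   weights)`.  It follows analytically that VIP drive alone disinhibits
   both PE neurons (baselines rise by `U * sum(w) * delta / (1 - v)`), SOM
   drive alone inhibits them by the same amount, and co-activation cancels.

An additional far-field bound keeps gamma_n large enough that the nPE soma
stays below threshold for strongly under-predicted stimuli even after its
dendrite rectifies.  Every constructed circuit is gated behind a response
validation (baseline rates, one-sidedness, positive gains); construction
fails loudly if the constraint solve leaves the non-negative weight cone.

Local excitatory feedback from the PE somata onto the interneurons is
omitted; the somata project only to the memory and variance neurons.  This
keeps the interneuron subsystem autonomous, which makes the background
calibration and the balance solve exact.

**Background calibration.**  Target baselines are 0 /s for all four
excitatory compartments and 4 /s for the interneurons.  At that fixed point
the excitatory units sit exactly at threshold, so
`I_bg = r_target - W r_target` solves the steady state directly; the
calibration is verified by simulation to 0.01 /s and is idempotent.

## Numerics

Explicit second-order Runge-Kutta (Heun) at dt = 1 ms, rates re-rectified
at both stage evaluations, all rates initialized at zero.  dt/tau_I = 0.5
is well inside Heun's stability region, and endpoint errors scale as
dt^2 (measured ratio ~16 per fourfold refinement).  The inner loop is
JIT-compiled (numba).  The variance rates are floored at zero after each
step (the floor only engages on start-up transients) and negative memory
excursions are counted and logged, not clipped, since stimuli may be drawn
negative by the normal family.  Steady-state probes integrate 3 s; the
PE "silent" threshold is 1e-3 /s.

## Stimulus generator

Protocols are two-timescale, piecewise-constant series: per-trial means
drawn from U(a, b) (variance (b-a)^2/12) or fixed; within-trial values
drawn from a normal (default) or moment-matched uniform distribution with
variance sigma2_in, each held for `steps_per_value` milliseconds.  One seed
spawns independent sub-streams for trial means and within-trial values, so
changing one component never reshuffles the other, and rendering is
bit-reproducible.  Negative draws are kept (their frequency is recorded);
the standard protocols make them rare.  A scalar-variability option sets
the within-trial standard deviation to k times the trial mean.  The
single-level estimation preset uses the uniform family; the hierarchy
presets use the normal family.

What the generator does *not* emulate: continuously varying signals,
non-uniform trial-mean distributions, temporally correlated noise, and any
observation noise downstream of the stimulus.  Tests passing on these
protocols show that the circuit implements the intended computation on
piecewise-stationary inputs, not that the computation is robust to real
sensory statistics.

## Experiment conventions

* **Steady-state sensory weight.**  Reported by applying the weighting
  formula once to the time-averaged variance rates over the last half of a
  run (`ratio_of_means`).  Averaging the instantaneous ratio (also
  available) is Jensen-biased downward when the variance rates fluctuate;
  both summaries are computed by the test suite.
* **Perturbations.**  Constant extra excitatory input to PV (both units),
  SOM and/or VIP, by default in both levels, switched on at a trial
  boundary.  Shifts are measured against an unperturbed control run with
  the same protocol and seed over the same late window, so the slow
  convergence of the higher memory neuron (tau ~ 86 s) cancels.  Strong PV
  input can silence the PE population entirely; the variance rates then
  decay to zero and the weighting ratio becomes uninformative, so analyses
  report the remaining variance-signal fraction alongside each shift.
* **Contraction bias.**  Per-trial bias is the trial-averaged difference
  between the weighted output and the stimulus; the regressor is the
  trial's realized mean stimulus (well defined even with fixed trial
  means), with the drawn trial mean available as an option.  The first
  quarter of trials is discarded as transient.  On the closed-form regime
  `r_out = a s + (1 - a) mu_bar` the fitted slope is exactly -(1 - a).

## Known limitations

* The variance neuron under-estimates the stimulus variance by ~10% under
  the 500-ms-segment protocols: the PE somata respond with tau_E = 60 ms,
  so each segment loses the first ~2 tau_E of squared-mismatch mass.  The
  deficit is physics of the stated time constants (it is dt-independent and
  disappears against the idealized oracle when the segment duration grows).
* On the matched-variance diagonal the steady-state weight settles slightly
  below 0.5 (~0.46-0.48): change-point transients contribute
  2 sigma2_trial * tau_M / T_trial of extra mass to the lower variance
  estimate while the higher one loses the tracked part.  The equal-variance
  benchmark passes within its 0.05 band, but the deviation is systematic.
* With zero stimulus noise the weight is high but not 1 (~0.74 under the
  volatile-environment preset): the same change-point transients keep the
  lower variance estimate from vanishing.
* Scaling both memory weightings jointly changes the weight only somewhat
  less than scaling the lower one alone: the higher variance estimate is
  nearly independent of the higher memory timescale once that timescale is
  much slower than the environment, so the compensation the joint scaling
  provides is weak.
* Interneuron rectification bounds the linear mismatch range to roughly the
  operating point (|s - p| up to about the mean input level); beyond it the
  PE response curves kink.  Trial-onset transients in volatile protocols
  enter this range briefly.
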