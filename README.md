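# pecircuit

A rate-based simulator of hierarchical prediction-error circuits that
estimate the mean and the variance of their sensory inputs, weight raw
stimuli against internal predictions by their reliabilities, and reproduce
neuromodulatory biases of that weighting as well as the contraction bias of
perceptual estimation.  It is aimed at computational neuroscientists who
want a tested, scriptable implementation of this model family for
simulation experiments and method comparisons.

## The model

The core is an eight-unit mean-field microcircuit: the somata (nE, pE) and
dendrites (nD, pD) of a negative and a positive prediction-error (PE)
neuron, two PV interneurons, one SOM and one VIP interneuron.  Rates follow

    T_c dh/dt = -h + W r + w_fb * p + w_ff * s + I_bg,      r = [h]_+,

with tau_E = 60 ms for excitatory units, tau_I = 2 ms for interneurons,
feedforward stimulus `s`, feedback prediction `p`, and complementary routing
`w_ff = 1 - w_fb` (PV targets somata, SOM targets dendrites, SOM and VIP
inhibit each other and the PV units).  Three wirings (MFN1-3) differ in
whether SOM and VIP receive `s` or `p`.  The intra-circuit weights are not
hand-picked: they are solved from the multi-pathway excitation/inhibition
balance so that fully predicted inputs silence both PE somata, mismatches
evoke one-sided responses (nE for `s < p`, pE for `s > p`), and equal extra
drive onto SOM and VIP cancels at the PE neurons.

Each level feeds its PE rates into a memory neuron M (a perfect integrator;
its steady state is the exponential moving average of the input, effective
time constant tau_E / lambda) and a variance neuron V (a leaky integrator
with quadratic activation, tau_V = 5 s; its steady state is the input
variance).  The lower level sees the stimulus; the higher level sees the
lower memory rate and thus estimates the prediction's own uncertainty.  The
weighted output is computed arithmetically:

    r_out = alpha * s + (1 - alpha) * r_M_low,
    alpha = (1 + r_V_low / r_V_high)^-1.

## A worked example

```python
import pecircuit as pc

net = pc.build_network("MFN1", lambda_low=pc.LAMBDA_LOW_FIG2)
result = pc.run_simulation(net, pc.get_preset("fig2DE"), seed=0)
print(result.r_m_low[-10_000:].mean())   # 4.807
print(result.r_v_low[-10_000:].mean())   # 3.750
```

The protocol draws 200 stimulus values (500 ms each) with mean 5 and
variance 4.  After 100 s the memory neuron reads 4.81 - the running mean,
still carrying the few-percent lag of its 20-s effective time constant and
the sampling noise of the draw - and the variance neuron reads 3.75, the
stimulus variance minus the small loss from the PE neurons' 60-ms response
time.  The full two-level network weights its inputs by uncertainty:

```python
net = pc.build_network("MFN1")
for preset in ("fig3C", "fig3D", "fig3E"):
    res = pc.run_simulation(net, pc.get_preset(preset), seed=0)
    print(preset, pc.steady_state_alpha(res))
# fig3C 0.743   noise-free stimuli, volatile environment: trust the senses
# fig3D 0.184   noisy stimuli, stable environment: trust the prediction
# fig3E 0.476   matched variances: both streams weighted about equally
```

The scripts in `examples/` walk through each capability (circuit
validation, mean/variance estimation, uncertainty weighting, interneuron
neuromodulation, contraction bias); each prints a few numbers and says what
they mean.  A thin CLI covers the same ground from a shell:

```
pecircuit validate-circuit --variant MFN1
pecircuit simulate --preset fig3C --seed 1 --outdir results
pecircuit sweep --grid 6 --sigma2-in 0:25 --sigma2-trial 0:25
pecircuit perturb --regime sensory
pecircuit bias --preset fig5A_low
```

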