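"""The contraction bias: outputs gravitate toward the mean of past stimuli.

Because the weighted output mixes the stimulus with the (history-averaged)
prediction, trials below the distribution mean are over-estimated and trials
above it under-estimated.  The slope m of bias versus trial stimulus
measures the pull; |m| grows with stimulus noise and shrinks with
environmental volatility and with trial duration.
"""

import pecircuit as pc

net = pc.build_network("MFN1")

conditions = {
    "low stimulus noise     (var 1)": pc.get_preset("fig5A_low", n_trials=100),
    "high stimulus noise    (var 4)": pc.get_preset("fig5A_high", n_trials=100),
    "longer trials          (10 s) ": pc.get_preset("fig5C_narrow", n_trials=100,
                                                    steps_per_value=1000),
}
for label, proto in conditions.items():
    res = pc.run_simulation(net, proto, seed=0)
    bias = pc.compute_bias(res)
    print(f"{label}: m = {bias.slope:+.4f}")

res = pc.run_simulation(net, pc.get_preset("fig5A_low", n_trials=100), seed=0)
table = pc.compute_bias(res).table
below = table[table.trial_stimulus < 19].bias.mean()
above = table[table.trial_stimulus > 21].bias.mean()
print(f"mean bias below the distribution mean: {below:+.3f}")
print(f"mean bias above the distribution mean: {above:+.3f}")

# A negative slope is the contraction: positive bias low in the range,
# negative bias high in the range, stronger when the stimulus is noisy and
# weaker when trials are long enough for the output to converge.
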