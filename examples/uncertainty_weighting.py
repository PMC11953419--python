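"""Uncertainty-weighted integration of stimulus and prediction.

The two-level hierarchy estimates the stimulus variance (lower level) and
the prediction variance (higher level); their ratio sets the sensory weight
alpha = r_V_high / (r_V_low + r_V_high).
"""

import pecircuit as pc

net = pc.build_network("MFN1")

for label, preset in [
    ("noise-free stimuli, volatile environment", "fig3C"),
    ("noisy stimuli, stable environment       ", "fig3D"),
    ("equal variances (both 5)                ", "fig3E"),
]:
    res = pc.run_simulation(net, pc.get_preset(preset), seed=0)
    alpha = pc.steady_state_alpha(res)
    print(f"{label}: alpha = {alpha:.3f}")

# alpha near 1 means the output tracks the raw stimulus, near 0 that it
# tracks the internal prediction; with matched variances the two input
# streams contribute about equally (alpha ~ 0.5).
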