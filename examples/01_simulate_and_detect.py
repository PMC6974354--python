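"""Simulate one layer 5 neuron and detect its calcium transients.

Generates raw fluorescence for soma, trunk segments and tuft; converts each
trace to dF/F0 with the 5th-percentile smoothed baseline; detects peaks above
2.8 x noise SD; and compares detected counts with the generator's hidden
ground truth.  The per-compartment counts should fall off with distance from
the soma (distance-dependent attenuation of back-propagating events).
"""

from cacoupling import (SynthConfig, compute_dff, detect_events,
                        estimate_noise_sd, generate_neuron)

config = SynthConfig(duration=600.0, fs=5.0, soma_event_rate=6.0, seed=42)
traces, truth = generate_neuron(config)

print(f"{'compartment':>12} {'true':>6} {'detected':>9} {'noise_sd':>9}")
for comp, raw in traces.items():
    dff = compute_dff(raw)
    noise = estimate_noise_sd(dff)
    events = detect_events(dff, noise)
    print(f"{comp:>12} {truth.count_in(comp):>6} {len(events):>9} {noise:>9.4f}")

n_soma = truth.count_in("soma")
print(f"\nground-truth frequency ratio tuft/soma: "
      f"{truth.count_in('tuft') / n_soma:.2f}")
print("(< 1 because small, low-burst-frequency somatic events attenuate "
      "before reaching the tuft)")
print("detected counts exceed truth at this noise level: with no minimum "
      "inter-peak distance, noise riding a transient's decay can produce "
      "duplicate local maxima above threshold")
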