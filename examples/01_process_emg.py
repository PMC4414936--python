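"""Condition a raw surface-EMG trace into a muscle-activation signal.

Builds one synthetic flexion-hold-extension trial, runs the causal
conditioning chain (high-pass, rectify, recursive activation dynamics,
low-pass, MVC normalization, exponential nonlinearity) and prints where the
activation sits in each movement phase.
"""

import numpy as np

from myoelbow import (
    PipelineConfig,
    SyntheticSubject,
    TrajectorySpec,
    compute_mvc,
    generate_dataset,
    process_to_activation,
)

config = PipelineConfig()
trials, mvc_trial = generate_dataset(TrajectorySpec(), SyntheticSubject(seed=0), 1)
raw, angles = trials[0]

mvc_value = compute_mvc([mvc_trial], smooth_cutoff=config.lowpass_cutoff)
activation = process_to_activation(raw, mvc_value, config)

fs = raw.sampling_rate
print(f"MVC envelope peak: {mvc_value:.3f} (raw units)")
for label, t in [("rest", 0.1), ("mid-flexion (45 deg)", 1.5),
                 ("holding (90 deg)", 4.5), ("mid-extension (45 deg)", 7.5)]:
    i = int(t * fs)
    print(f"  t = {t:4.1f} s  {label:24s} a = {activation.samples[i]:.3f}")
print(
    "The activation is a fraction of maximal drive: near zero at rest, "
    "rising through flexion (with the concentric overshoot), and settling "
    "on the isometric plateau during the hold."
)
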