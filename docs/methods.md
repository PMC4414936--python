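# Methods

## Problem and scope

The package estimates voluntary elbow flexion/extension angle (0° = arm
hanging, 90° = forearm horizontal) in the sagittal plane from one biceps
surface-EMG channel sampled at 1000 Hz.  Three contraction regimes occur in
one movement: concentric (flexion), isometric (holding) and active
lengthening (extension).  Triceps and brachialis contributions, fatigue,
multi-channel recordings and hardware control loops are out of scope.

## Signal model and conditioning chain

All filters are causal; the output is meant as a real-time control
reference, so zero-phase filtering is never used, including during
calibration — calibration and prediction must see the same latency.

| stage | default | units | why |
|---|---|---|---|
| high-pass Butterworth | 10 Hz, order 4 | — | removes DC offset and motion artefact before rectification |
| rectification | full-wave | — | amplitude demodulation |
| activation dynamics | γ₁ = γ₂ = −0.5, d = 50 samples | poles, samples | second-order recursive filter u(t) = αe(t−d) − β₁u(t−1) − β₂u(t−2); the constraint α − β₁ − β₂ = 1 pins the DC gain to 1 so excitation cannot exceed 1 after MVC normalization.  d models the electromechanical delay; 50 ms is a mid-range physiological value |
| low-pass Butterworth | 1.0 Hz, order 2 | — | muscle force cannot follow the EMG amplitude bandwidth; the cut-off is kept in the 0.5–1 Hz band.  We default to the top of that band because this filter's group delay (≈ 0.22 s at 1 Hz vs 0.28 s at 0.8 Hz) is the dominant control latency, and at 30°/s ramps latency converts directly into tracking error |
| MVC normalization | peak smoothed envelope over the MVC trials | — | puts excitation on a per-subject [0, 1] scale; values above 1 are clamped |
| nonlinearity | A = 0.5, R = 1/A = 2 | — | a(u) = (e^(u/R) − 1)/(e^A − 1).  The quadratic calibration relation is derived in the excitation variable, so the excitation-to-activation shape must stay close to linear for a quadratic in a/R to represent the composed relation; A = 0.5 is mildly convex and preserves a(0) = 0, a(1) = 1 |
| dead-band rectification | 2 % (range 1–3 %) | relative | staircase that holds its output until the input moves more than dead_band × held value (absolute floor dead_band near zero).  Stabilizes the relaxation state and the trend classification against envelope wobble.  A value of 0 disables it (used only by noise-free closed-loop tests; a 1 % activation step near 90° already maps to several degrees) |

## Calibration

One trial with recorded angles is processed through the full chain; the
flexion phase is detected from the smoothed angular velocity (> 5°/s,
runs ≥ 200 ms) and cos²θ is regressed on x = a/R with a quadratic.

The fit is **weighted by the local angle sensitivity** 1/sin 2θ (capped at
sin 2θ ≥ 0.1): the model is consumed through θ = arccos √(·), whose
sensitivity to cos²θ-residuals diverges at 0° and 90°; an unweighted fit
leaves ~0.02 residuals near the top of the range that translate into ~8°
errors at the 90° hold.  The weighting approximately minimizes
angle-domain error instead.  `fit_r` is the Pearson correlation between
fitted and observed cos²θ on the flexion samples.

Thresholds derived from the same trial: holding threshold
F_t = κ × peak flexion activation (κ = 0.9 default), inactivation level
max(dead_band, 5 % of peak).  The model also stores the release band a_r
(the dead-band value): holding releases into extension when activation
falls below F_t(1 − a_r).

Calibration is deliberately *not* latency-compensated.  Pairing the lagged
activation with the simultaneous recorded angle lets the fitted map absorb
the chain latency for the calibrated movement direction, which is what
keeps held-out continuous trials accurate; compensating the known group
delay was evaluated and traded flexion accuracy for descent accuracy at a
net loss.

## State switching model

States: relaxation → flexion → holding → extension → {relaxation, flexion}.

* relaxation outputs 0°, leaves on a rising trend with a > inactivation;
* flexion outputs the inverse map and remembers its last output as θ_max;
  it enters holding when the trend stops rising while a > F_t;
* holding outputs θ_max frozen; it exits to extension on the threshold
  crossing a < F_t(1 − a_r).  A slope-based "falling" test was rejected:
  the threshold-crossing semantics is the only operational definition
  consistent with the peak-lag law t_lag = (F_p − F_t(1 − a_r))/γ and it is
  insensitive to plateau wobble;
* extension outputs clamp(p·invert(a), 0°, 90°) with p = θ_max/θ′_max fixed
  at entry (θ′_max = inverse map at the first extension sample), making the
  output continuous across the switch; p saturates at p_max = 3 with a
  warning if θ′_max degenerates.  Extension returns to relaxation at the
  inactivation level, or to flexion on a rising trend.

Trend classification: least-squares slope over a trailing 250 ms window of
the dead-banded activation; a trend requires the signal to move two
dead-band widths per window, and a raw classification must persist 100 ms
(debounce) before the reported trend switches.  Without the debounce,
envelope wobble flickers the automaton between holding, extension and
flexion during long holds.

`run` is exactly a fold of per-sample `step` calls (verified by test), so
the model is streaming-capable at the EMG rate.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, not a
motor-unit-level simulation:

* **trajectories**: trapezoid 0→90° at 30°/s with a 3 s hold, or staircases
  of 10/20/30° increments with 3 s holds, mirroring the experimental
  protocol the method targets;
* **envelope**: exact inverse of a known monotone quadratic
  activation→cos²θ map (default (1, −2.2, 0.8), i.e. the 90° hold demands
  ≈ 0.57 of maximal drive), multiplied by an overshoot factor 1.15 while
  the angle rises, relaxing back with τ = 150 ms — reproducing the
  rapid-drop-then-plateau at the flexion→holding boundary.  The envelope
  leads the angle by 50 ms: real EMG precedes motion by the
  electromechanical delay, which is exactly what the chain's delay d
  models; omitting the lead would double-count it;
* **carrier**: zero-mean Gaussian noise band-passed to 20–450 Hz and scaled
  to unit variance — the standard surface-EMG interference model —
  amplitude-modulated by the envelope;
* **jitter**: multiplicative 1 + j(t) with j Gaussian low-passed at 2 Hz
  and rescaled so its s.d. equals `envelope_jitter` (default 0.05).

What the generator does **not** emulate: electrode-shift artefacts, fatigue
drift, crosstalk, the true activation–EMG relation during active
lengthening (the same map is applied on descent), or motor-unit
discretization.  Passing tests therefore demonstrate correctness of the
estimation chain under the stated signal model, not performance on human
recordings.

A consequence worth knowing: even with `envelope_jitter = 0`, the smoothed
amplitude of band-limited Gaussian noise has an irreducible ~2–3 % relative
s.d., which puts a floor of roughly 2–2.5° RMS on held-out flexion
tracking, and the MVC normalizer (a *peak*) sits ~6 % above the envelope
mean.

## Error anatomy on the synthetic protocol

Mean RMS on held-out continuous trials is typically 7–9°, composed of:
onset (output pinned at 0° until activation clears the inactivation gate,
which the flat cos²θ near 0° pushes to ~20–25° of true angle), ramp
tracking (small — calibration absorbs the chain latency for the calibrated
direction), hold (map residual at the 90° singularity plus occasional
wobble-induced state flips), and extension (largest: the latency absorbed
by the calibration enters with the opposite sign on descent, partly offset
by the absent overshoot).  Stepping movements score better (6–8°) because
settled holds dominate.  These structural error sources are inherent to a
causal, single-channel, statically calibrated method.

## Numerical choices and degenerate inputs

* Butterworth filters are designed as second-order sections; the recursive
  activation dynamics is evaluated exactly as the printed difference
  equation (verified against a brute-force loop).
* sinh overflow in the force–velocity curve is guarded at |2.8v + 1.64| > 7,
  where the analytic asymptotes (0 and 0.1433/0.1074) are already exact in
  double precision.
* The generator's envelope inversion uses the exact quadratic root branch
  through a = 0 in a cancellation-free form; targets below the map's
  reachable minimum clamp to the vertex.
* Inverse-map outputs clamp cos²θ to [0, 1] rather than rejecting, since
  noise routinely pushes the polynomial outside the range; outputs are
  always in [0°, 90°].
* Degenerate cases raise typed errors: unstable poles, zero MVC, constant
  calibration activation, missing flexion segment, non-uniform time
  columns; a non-monotone fitted map is flagged with a warning on the model
  rather than rejected.

## Problem sizes

Tests and the acceptance script use the full protocol sizes: 9 s continuous
trials and 24–36 s stepping trials at 1000 Hz, 10 trials per condition,
20 calibration datasets of 500 samples.  The complete acceptance run takes
≈ 10 s on one CPU.

## Known limitations

* The relaxation gate plus the flat cos²θ near full extension creates a
  dead zone of ~20° at movement onset; the paper-style protocol shares it.
* The proportional extension gain is a single scalar; it guarantees
  continuity at the switch but over-corrects mid-range descent angles.
* Holding at exactly 90° sits on the arccos singularity; small map
  residuals there cost several degrees (mitigated by the weighted fit).
* Thresholds are calibrated once per session; non-stationarity (electrode
  shift, fatigue) is not tracked.
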