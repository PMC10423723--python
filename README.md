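# stereovr

A virtual-reality stereopsis assessment pipeline with eye tracking, built
for studying visual and cognitive effects of Post-COVID syndrome (and
other neurophysiological conditions) from a short stereoscopic task.

The assessed task shows four balls at 200 cm; one ball is rendered nearer
so that the binocular disparity difference Θ between it and the others is
a multiple of the headset's pixel quantum — 275″ on a 110° / 1440 px
display, since `dd_min = FoV / n_pixels · 3600″`. The participant presses
an arrow key for the nearer ball as fast as possible, over 81 stimuli
(Θ ∈ {275″, 550″, 1100″} × 9 test positions × 3 repetitions, random
order), while a ~90 Hz eye tracker records pupil diameter, gaze origin
and direction and eye openness for both eyes.

The package implements everything downstream of the headset, plus a
synthetic-cohort generator standing in for (private) patient data:

- **geometry** — disparity quantization, stimulus placement in spherical
  coordinates, the closed-form solution of the near-ball distance D from
  Θ (via `tan(Θ+Φ_B)·D² + (l₁−l₂)·D + tan(Θ+Φ_B)·l₁·l₂ = 0`), monocular-cue
  corrections (size scale `s = D/D_total`, positional jitter) and seeded
  trial schedules.
- **preprocess** — blink masking (openness < 0.1), the four staged pupil
  validity filters (physiological range 1.5–9.0 mm, dilation-speed and
  trend-deviation MAD outliers, isolated clusters), two-eye merge with
  shape-preserving PCHIP gap interpolation, and gap-limited linear gaze
  interpolation.
- **gaze / pupil metrics** — per-eye angular velocity with an asymptotic
  (exponential-relaxation) smoother, velocity-threshold fixation
  detection, per-ball dwell times; the Low/High Index of Pupillary
  Activity (LHIPA, a wavelet-band modulus-maxima ratio — lower = more
  pupil oscillation = higher inferred cognitive load) and two-part
  regression slopes per stimulus.
- **features** — the 73-feature vector per run: 29 stereopsis-performance
  features (reaction-time moments on correct responses, accuracy and
  median-RT gains per disparity), 18 pupil features, 26 gaze features.
- **classify** — nested cross-validation: stratified 5-fold inner grid
  search (linear/RBF SVM, kNN, random forest with fixed grids) inside an
  outer leave-one-out loop, min-max scaling and median imputation fitted
  strictly on training folds, confusion matrices, hyperparameter
  frequency tables and a top-10 feature ranking.
- **simulate** — a seeded generator of raw eye-tracking logs and
  responses for control-like and patient-like participants, with
  configurable group effects (slower/less accurate responses, slower
  gaze, longer fixations, more pupil oscillation at 275″) and stored
  ground truth.

## Worked example

```bash
python examples/01_stimulus_geometry.py
```

prints the solved geometry of the default design:

```
disparity quantum: 275.0" per pixel

Θ (arcsec)   D (cm)    Δd (cm)   size scale s   round-trip Θ
       275    191.83      8.17       0.9591        275.000
       550    184.33     15.67       0.9217        550.000
      1100    170.98     29.02       0.8549       1100.000

schedule: 81 stimuli (3 disparities x 9 positions x 3 repetitions), seeded random order
```

i.e. at the hardest level the near ball sits only 8.2 cm in front of the
far balls and is scaled to 95.9 % size to cancel the monocular size cue;
re-deriving Θ from each solved D reproduces the input exactly. The other
examples simulate a run and clean it (`02`), extract and compare feature
vectors for a control and a patient profile (`03`), and run the
classifier bench on a small cohort (`04`). A thin CLI wraps the same
API: `stereovr simulate|features|bench|run|show-config`.

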