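# Methods

This note documents the models, parameter choices and numerical
decisions behind `stereovr`, and what the synthetic-cohort tests do and
do not demonstrate.

## Stimulus geometry

A disparity difference Θ (arcsec) between the near ball and the three
far balls at `D_total = 200 cm` is realized by placing the near ball at
distance D solving Θ = Φ_A(D) − Φ_B, where Φ_B = 2·atan(a / 2·D_total)
is the far-ball disparity for interpupillary distance a (default
6.3 cm, adequate because D_total ≫ a) and Φ_A = atan(l₂/D) − atan(l₁/D)
with l₁ = |e|, l₂ = |e| + a for a horizontal shift e of the near ball.
The tangent subtraction identity turns this into the quadratic
`c₁D² + c₂D + c₃ = 0` (c₁ = tan(Θ+Φ_B), c₂ = l₁−l₂, c₃ = c₁l₁l₂), whose
root inside (0, D_total) is the solution; with the default e = 0 it
degenerates to the well-conditioned D = a / tan(Θ+Φ_B). If both roots
ever fall in range, the larger is taken (continuity with the Θ→0 limit,
where D → D_total). Unit handling is exact: 1″ = π/648000 rad. A
bisection oracle on the un-transformed equations and a Θ-recovery
round-trip (|ΔΘ| < 0.5″) guard the algebra in the tests.

Renderable disparities are integer multiples of the pixel quantum
`dd_min = FoV/n_pixels·3600″` (275″ at 110°/1440 px); requests below
half a quantum are rejected rather than silently rounded to zero.

Stimulus placement supports two spherical-to-Cartesian variants: the
`printed` form r·(cosθ, sinφ·cosθ, −cosφ·sinθ), and the default
`corrected` form r·(cosθ, sinφ·sinθ, −cosφ·sinθ) whose norm equals r
for every azimuth — the design intent, since all test positions are
specified to lie 200 cm from the observer. (The printed form inflates
the radius to r·√2·cosθ at φ = 90°.) Coordinates are x-forward,
y-right, z-up.

Monocular-cue corrections: the near ball is scaled by s = D/D_total
(size cue) and every ball receives an independent uniform [0, 2] cm
offset with random sign — horizontal for the Left/Right balls, vertical
for Up/Down — to veil linear perspective.

## Signal cleaning

Blinks are samples where either eye's openness < 0.1; no temporal
padding is applied by default (configurable). The pupil filter cascade
is the staged validity approach of standard pupillometry preprocessing:

1. physiological range, 1.5–9.0 mm;
2. dilation-speed outliers: the max of backward/forward sample-to-sample
   |Δd/Δt|, thresholded at median + 16·MAD;
3. trend-line deviation: residuals from a smoothed trend (PCHIP fill of
   provisionally valid samples, then a 0.3 s quadratic Savitzky-Golay
   smoother — chosen for its unbiased boundary handling), thresholded
   at max(median + 16·MAD, 0.05 mm). The absolute floor matters on
   low-noise signals, where the MAD collapses and a bare relative
   threshold would flag physically negligible (≪ 0.05 mm) residuals;
4. isolated clusters: valid runs shorter than 50 ms separated from
   neighbouring data by more than 40 ms on both sides.

Each stage only removes validity (tested as a mask-monotonicity
property). The two eyes are averaged where both are valid (single-eye
fallback otherwise) and remaining gaps are filled with shape-preserving
piecewise-cubic (PCHIP) interpolation — monotone across gaps, no spline
overshoot — with nearest-value fill at the edges, so the mean-pupil
signal is complete at every timestamp. Gaze gaps of at most 10 samples
are filled by componentwise linear interpolation and re-normalized;
longer gaps stay missing and no velocity is computed across them (the
10-sample limit is the parameter; at 90 Hz it corresponds to ≈111 ms).

## Gaze metrics

Angular change between consecutive unit gaze directions is
arccos(clamped dot product); dividing by the frame interval gives the
instantaneous velocity, and an asymptotic filter relaxes toward it with
per-frame rate α = 0.6 (config-exposed; the raw trace is also kept so
the filter can be disabled). The smoothing state resets after every
gap. Fixations are maximal runs with smoothed velocity below 30 deg/s
(the conventional velocity-threshold value) lasting ≥ 100 ms; both
parameters are exposed because the upstream model leaves them open.
Everything is computed per eye — no cyclopean averaging — and dwell
times accumulate the frame intervals of the tracker's fixated-ball
label channel per label (Up/Down/Left/Right/background).

## Pupil metrics

**LHIPA.** The mean-pupil segment is wavelet-decomposed; the elementwise
ratio of the low-frequency detail band (level ⌊maxlevel/2⌋) to the
level-1 high-frequency band is formed (the high band sampled at the low
band's stride), its modulus maxima are thresholded with the universal
threshold λ = σ·√(2·log₂ n) keeping sub-threshold maxima, and the count
of survivors is divided by the segment duration. Lower values mean
relatively more high-frequency oscillation, read as higher cognitive
load.

Two consequences of short segments at 90 Hz drove design choices:

- *Wavelet*: the default is **sym4**. With a 32-tap symlet the low band
  only separates from level 1 once a segment exceeds ≈496 samples
  (5.5 s) — longer than a typical response window — whereas sym4 needs
  112 samples (≈1.25 s). Longer wavelets remain available via
  configuration for minute-scale signals.
- *Missing policy*: a segment whose decomposition depth gives no
  distinct low band yields no index (missing) rather than a degenerate
  constant. In particular the 1 s idle-phase baseline window (90
  samples) is below the sym4 threshold, so the baseline feature is
  reported missing at 90 Hz; it stays in the vocabulary and is imputed
  like any other missing feature.
- *Scale invariance*: the index is invariant to uniformly rescaling the
  signal's noise, because the threshold is derived from the maxima
  themselves. What lowers it is a *coherent* fast oscillation rising
  above the measurement-noise floor — this is how the generator encodes
  "more oscillatory pupil signal" (below). A mathematically noise-free
  signal is a degenerate input for modulus-maxima counting and is not a
  meaningful reference point; comparative tests therefore always
  include a realistic noise floor.

**Slopes.** Each stimulus segment (onset → response; variable length) is
split at its temporal midpoint and an OLS line fitted to each half. The
first half may still carry the delayed pupil response to the previous
stimulus; the second half is the cleaner readout of the current one.
Per-disparity means of both slopes give six features.

## Feature vocabulary (73 = 29 + 18 + 26)

- *Stereopsis performance* (29): per disparity, the maximum, minimum,
  mean, median, SD, variance, skewness and kurtosis of reaction time on
  **correct responses only**, plus accuracy = correct/27; two gains:
  median RT at 275″ (and 550″) minus median RT at 1100″, canceling the
  individual base response time (positive = slowing on harder tasks).
- *Pupil diameter* (18): the eight statistics of the whole-run mean
  pupil signal, four LHIPA features (baseline + three per-disparity
  means), six slope features. All from the merged signal, never per eye.
- *Gaze behavior* (26): per eye, fixation count, seven velocity
  statistics (the minimum is excluded — it is zero for everyone), and
  five dwell durations (four balls + background).

Conventions, fixed for reproducibility and config-switchable:
population (n-denominator) SD/variance; skewness and excess (Fisher)
kurtosis as biased moment estimators. Degenerate shape moments (zero
variance) are missing. Feature names follow the
`Statistic_Disparity` / `Statistic_Eye` / `Target_Fixation_Duration_Eye`
pattern so group-level reports are directly comparable across runs.
Features that cannot be computed are median-imputed inside each
training fold of the classifier bench (leave-one-out needs complete
vectors; imputing per fold avoids leakage).

## Classification bench

Outer loop: leave-one-out over participants. Inner loop: stratified
5-fold grid search (shuffle on, fold seed 0), scoring plain accuracy,
ties broken by grid enumeration order. Grids: linear SVM C = 2^N and
RBF SVM C, γ = 2^N for N ∈ [−10, 10]; kNN 3–15 neighbours ×
{uniform, distance}; random forest max_depth ∈ {2,4,6},
min_samples_split ∈ {2,4,6}, min_samples_leaf ∈ {1,2,4} with 300 trees,
√(n_features) feature subsampling and bootstrap on. Classifier
random_state is 0. Median imputation and min-max scaling are refitted
inside every fold (inner and outer) on training data only; evaluation
values may fall outside [0, 1] (no clipping), and zero-range features
map to 0. Grid points infeasible for a small fold (k > n_train) are
skipped. Accuracy on an N-participant cohort has granularity 1/N, so
confusion matrices rather than standard deviations carry the error
structure. Feature importance (default: impurity importance of a
300-tree forest, averaged over the outer training folds so it never
sees a held-out participant) yields a top-10 report; the ranking is
never used to prune features. The full 4-classifier × 4-group bench is
exact but compute-heavy — the RBF-SVM grid has 441 points and a single
forest cell costs tens of minutes of single-core time — so the examples
and acceptance checks exercise the fast classifiers and leave the full
cross-product to explicit CLI runs.

## Synthetic cohort

The generator emulates a pilot-scale case-control cohort (default 15
controls + 20 patients) at the raw-channel level, with per-participant
random effects around each group profile and all ground truth stored:

- *Responses*: reaction time is lognormal with median
  `rt_base + step·rt_slope + group_shift` (step = 0, 1, 2 for 1100″,
  550″, 275″; defaults 1.6 s + 0.3 s/step, patient shift +0.35 s,
  log-scale σ = 0.25 — plausible second-scale stereoscopic decision
  times with a right tail, matching the use of skew/kurtosis features);
  correctness is Bernoulli per disparity (controls 0.97/0.90/0.80,
  patients 0.92/0.82/0.66, hardest last).
- *Gaze*: a fixation script scans the four balls (dwell ≈ 0.30 s ×
  `fixation_prolongation`, patients 1.35×) ending on the answered ball;
  transitions unfold at a saccade peak velocity of 250 deg/s ×
  `velocity_scale` (patients 0.75), with fixational jitter scaled the
  same way, so every velocity statistic scales with the single
  ground-truth factor. Per-frame directions derive from actual 3-D
  ball positions per eye; the fixated-label channel follows the script
  (background during saccades and between stimuli).
- *Pupil*: base diameter (4.2 ± 0.3 mm) + slow drift + a
  difficulty-dependent dilation transient (delayed ramp during the
  stimulus, slow decay after the response — what the slope features
  read) + measurement noise (per-eye σ = 0.02 mm) + a narrow-band
  23–28 Hz oscillation whose amplitude is 0.01 mm during ordinary
  stimuli and `hf_oscillation_gain` during 275″ stimuli (controls
  0.012, patients 0.05). The oscillation band sits inside the index's
  level-1 wavelet band at 90 Hz — a stylized carrier of "oscillatory
  instability under load" placed where second-scale segments can
  resolve it, not a physiological hippus model.
- *Artifacts*: Poisson blinks (0.2 Hz, 120–250 ms) dropping openness to
  0.02 and blanking pupil and gaze; 1 % random sample dropouts.

What passing tests show: the pipeline recovers injected artifacts,
Bernoulli rates and velocity scaling; group effects of the encoded
directions are detectable end-to-end (a strongly separated default
cohort reaches ≥ 90 % LOOCV accuracy; a zero-effect cohort stays at
chance under label permutation). What they do not show: performance on
real patients — the generator's effect sizes are illustrative, its gaze
scripts and pupil dynamics are stylized (no pupillary light reflex, no
vergence, no main-sequence saccade kinematics), and real cohorts carry
head-set-fit asymmetries and inter-eye correlations it does not model.
The pupil feature group discriminates only weakly by design (one
small-amplitude oscillation contrast), mirroring the clinical
observation that pupil features contribute least.

## Problem sizes in the checked runs

The test-suite and acceptance runs use the full 81-stimulus design and
full 35-participant cohorts for the end-to-end checks; classifier
cells exercised routinely are those with second-scale grids (kNN,
linear SVM), with the forest and RBF grids covered at reduced cohort or
grid size in unit tests. Monte-Carlo ensembles (filter recall, LHIPA
direction, permutation null) use 10–100 seeded repetitions.
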