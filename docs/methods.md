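# Methods

This note records the models implemented, the parameter choices that matter,
and the places where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The classification problem

A *recording* is one participant walking one route in one condition,
`familiar` or `unfamiliar`. The unit of classification is a 3-second window
taken from the *matching-to-action* phases of the walk — the stretches from
an instruction request ("turn left after …") to arrival at the junction the
instruction refers to, where instruction-triggered wayfinding behavior is
expected. Each window yields 28 gaze and 99 IMU descriptors; a
gradient-boosted tree classifier predicts the condition label, and
validation is participant-aware so that no window of a held-out recording
influences training.

## Synthetic sessions

The generator (`synthetic_data`) emulates the statistical structure of the
streams, not their visual content:

- **Gaze** (200 Hz, normalized scene units, origin top-left, x right,
  y down): a fixation–saccade renewal process. Fixation durations are
  log-normal (mean 250 ms, SD 100 ms); within a fixation, samples jitter
  around the centroid with a Gaussian SD set per condition
  (`fixation_dispersion_scale`, defaults 0.0011 / 0.0014). Saccade
  amplitudes are gamma (shape 2, scale 0.055 / 0.070 per condition) with a
  main-sequence-like duration (≈ 21 ms + 2.2 ms/deg) and uniform random
  direction, reflected into the scene.
- **IMU**: acceleration is synthesized at 400 Hz — a 1.5 m/s² gait sinusoid
  on the vertical axis at the step frequency (default 1.8 Hz, per-participant
  jitter SD 0.08 Hz), half-rate sway and double-rate bob on the lateral
  axes, plus white noise whose SD is condition-dependent (0.85 / 1.0 m/s²) —
  and reduced to the 100 Hz rotation clock with the same nearest-timestamp
  downsampler the pipeline exposes. Yaw is a participant baseline offset
  (SD 15°) plus a slow scanning oscillation (condition-dependent amplitude,
  defaults 10° / 15°, at 0.3 Hz) plus noise, wrapped to (−180°, 180°]. Yaw
  is generated relative to the travel direction; the route's heading profile
  is deliberately omitted so that the condition contrast is not confounded
  with route geometry.
- **Artifacts**: cap-touch bursts arrive as a Poisson process (default
  0.5/min); each is a 0.15–0.35 s half-sine pushing |free acceleration|
  15 % above the configured peak (default 15 m/s²) on all three axes. The
  injected intervals are kept as ground truth on the recording.
- **GNSS** (1 Hz): the nominal constant-speed walk along the polyline
  (1.3 m/s) plus isotropic Gaussian noise (SD 1.5 m), with occasional
  samples (p = 0.02) displaced by a ~30 m jump and flagged `inaccurate` —
  the synthetic counterpart of a lost RTK correction.
- **Events**: one instruction request per turn junction, 15–30 s before the
  nominal arrival and after the previous junction.

Default effect sizes are a realism judgment, not measured field values: the
contrasts were set once to plausible magnitudes (unfamiliar walkers scan
more, move less smoothly, fixate more diffusely and make larger saccades)
and are cleaner than real behavior — no weather, traffic, social
interaction, or route-geometry confounds. Passing calibration tests on this
generator therefore demonstrates that the *pipeline* is sound (no leakage,
chance-level accuracy under a null effect, correct attribution of a planted
effect), not that real streets yield the same accuracy. Setting both
conditions of every per-condition parameter equal (`EffectConfig.
null_effect()`) removes the class signal entirely by construction.

## Preprocessing

Fixed order: low-pass → SST scores → threshold classification → drop.

- **Low-pass**: zero-phase Butterworth, order 4, cutoff 5 Hz on the free
  acceleration channels. The cutoff preserves the gait band (< 3 Hz) while
  suppressing sample-level ringing; it is configurable.
- **SST change scores**: at each evaluation point the past trajectory
  (Hankel) matrix — lagged subseries of length 50 ending at t — is compared
  with the future one starting at t + 25 samples. Both matrices subtract one
  shared centering constant (the local mean over the combined span), which
  makes scores exactly invariant to constant offsets while keeping a step in
  the mean detectable. The score is 1 minus the mean squared cosine of the
  canonical angles between the two leading 2-dimensional subspaces: 0 for a
  stationary signal, large across a structural change. Scores can be
  evaluated on a stride (`step`, default 1; the pipeline uses 10 and holds
  scores between evaluations) — artifact bursts are sub-second, so a 0.1 s
  evaluation grid loses nothing.
- **Classification**: samples where the per-sample maximum of the three
  filtered |free-acceleration| channels exceeds 10 m/s² form candidate runs;
  a run is kept only if the SST score peaks (> 0.05) in its neighbourhood,
  and kept runs are dilated ±0.25 s to cover burst shoulders. Since only
  these neighbourhoods are consulted, the pipeline evaluates SST locally
  around candidate runs. Raising the threshold can only shrink the undesired
  set (tested monotonicity).
- **Dropping**: undesired intervals are removed from the IMU *and* gaze
  streams and appended to the recording's exclusion intervals; GNSS is left
  untouched. The operation is idempotent.
- **Time-offset refinement**: for recordings whose IMU clock is only known
  to 1 s, the yaw extremum (maximum |yaw − local median|) within ±1 s of the
  coarse event time gives the sub-second correction Δt = t_B − t_A. A flat
  window (prominence < 5°) is flagged unreliable rather than guessed.
- **GNSS repair**: each `inaccurate` sample is replaced by the weighted mean
  of its two predecessors and two successors with weights [1, 2, 2, 1]/6
  (nearer neighbours double); flagged samples within two samples of the ends
  are left unchanged with a warning. All positions are then projected onto
  the route polyline (nearest point, via shapely).

## Segmentation

Junction arrival is the first GNSS time within a radius (default 10 m) of
the decision-point vertex — a circular stand-in for junction decision areas
built from building footprints, which need cadastral data. Repeated requests
for the same junction extend a single segment from the earliest request.
Segments are clipped around exclusion intervals (one request may yield
several sub-spans), then cut into non-overlapping 3 s windows from the
segment start; a trailing remainder shorter than 3 s is discarded so every
window has identical length and feature semantics.

## Gaze features

Fixations: classical dispersion-threshold detection (I-DT). A candidate
window must span ≥ 100 ms; its dispersion (max x − min x) + (max y − min y)
must stay ≤ 0.02 normalized units; windows grow greedily sample by sample
and the scan resumes after each emitted fixation. Dispersion components Δx
and Δy are reported separately. Velocity-based detection is not offered —
200 Hz outdoor gaze is too noisy for it. The greedy scan is verified against
an exhaustive maximal-window oracle.

Saccades: the amplitude between consecutive fixation centroids is corrected
for head rotation. The published analysis estimated head rotation from scene
-video homographies; no scene video exists here, so the rotation is taken
from the IMU orientation change across the inter-fixation gap and mapped to
scene units via a degrees-per-unit calibration (default 82°/unit from a
nominal 82° field-of-view scene camera; yaw right shifts a world-fixed
target left, pitch up shifts it down in the y-down convention). This is the
package's largest departure from the original procedure and is flagged here
deliberately. Missing IMU coverage yields the uncompensated amplitude,
flagged.

Per window: mean/min/max/sample-variance of fixation duration, dispersion,
Δx, Δy (16), fixation frequency, the same four statistics of saccade
amplitude and duration (8), adjusted Fisher–Pearson amplitude skewness,
saccade frequency, and the g-l ratio — long vs short saccades split at the
recording's median amplitude (undefined split or empty denominator → NaN).
28 descriptors; statistics needing ≥ 2 (or 3) events are NaN in sparser
windows, and the gradient-boosted learner consumes NaN natively. Published
model summaries count 26 gaze features while the descriptor table lists 28;
which two were dropped is not recorded, so all 28 are emitted and column
selection is left to configuration.

## IMU features

All 99, in six families (31 + 50 + 5 + 1 + 8 + 4). "Relative" channels are
mean-centered over the whole recording before windowing, because the
device's seat on the head differs between trials; window statistics of the
recording-centered channels are then informative (a window's local mean is
not removed).

- **Basic (31)**: min/max/mean/var of relative acc_x/y/z and roll/pitch/yaw;
  yaw frequency change — read as the zero-crossing rate (Hz) of the centered
  yaw, an interpretation choice recorded here; point-to-point amplitudes of
  the three acceleration and three free-acceleration channels.
- **Cepstral (50)**: real cepstrum of the acceleration magnitude
  √(ax²+ay²+az²) — inverse FFT of log(|spectrum|² + ε), ε = 1e-12 — first 50
  coefficients with c₀ included. Scaling the signal by k shifts only c₀ (by
  2 ln k).
- **Time-domain (5)**: std, energy ∫s²dt (= Σs²/fs), min, max, peak-to-peak
  of the magnitude signal.
- **Fundamental period (1)**: smallest interval between successive peaks of
  the magnitude signal, a step-cadence proxy. Peaks must clear a prominence
  of 0.5 × window std after band-limiting at 5 Hz (the same gait-preserving
  cutoff as preprocessing) so that sample noise does not register as peaks;
  fewer than two peaks → NaN.
- **Movement (8)**: movement intensity MI = √(ax²+ay²+az²) summarized by
  mean and (population) variance; signal magnitude area
  Σ(|ax|+|ay|+|az|)Δt / T; per-axis energy Σs²/N; Shannon entropy (bits) of
  a 16-bin histogram of MI over the window (binning is a documented choice);
  movement variation Σ(|Δax|+|Δay|+|Δaz|)/N.
- **Spectral/music (4)**: zero-crossing rate of the centered magnitude
  (crossings per sample pair); spectral centroid Σf|S|/Σ|S|; spectral
  rolloff (smallest frequency holding 85 % of spectral energy); chroma mean
  — the magnitude spectrum projected onto 12 log-spaced bins spanning
  0.5–50 Hz and averaged. Musical semitone bins are meaningless at a 100 Hz
  sampling rate; log-spaced bins keep the descriptor's spirit (energy
  distribution across octave-like bands) and that substitution is an
  interpretive choice.

Every family is verified against an independent, definition-level
implementation (explicit DFT sums, textbook formulas) to ≤ 1e-9 relative on
seeded random windows, and each feature's behavior under signal scaling
(invariant / linear / quadratic / additive-in-log) is declared and tested.
Published model summaries list 46 IMU features in the fitted models against
99 extracted; no selection rule is stated, so none is invented — models
train on all 99 by default and a feature-subset configuration is available.

## Classification and validation

- **Learner**: XGBoost binary logistic regression trees, log-loss metric,
  single-threaded and seeded for bit-reproducibility.
- **Outlier filter**: per-column mean/SD are fit on the training rows of
  each split; rows with any |z| > 3 are dropped from train and test alike.
  NaN never triggers removal.
- **Splits**: `split_8020` is a window-level stratified 80/20 split.
  `l5o4t` holds out all windows of 5 randomly drawn participants'
  *familiar* recordings and — independently drawn — 5 participants'
  *unfamiliar* recordings; the draw is independent per condition because
  familiarity is hypothesized to change behavior within a person. Repeats
  (default 10) redraw the holdout; average/best/worst accuracies are
  reported. A leakage assertion at fit time (not convention) verifies no
  held-out (participant, condition) pair contributes training rows.
- **Tuning**: selection by mean cross-validated negative log-likelihood
  (default 10 folds) over a hyperparameter grid. The default grid is the
  per-parameter union of published winning configurations (subsample,
  n_estimators, min_child_weight, max_depth, learning_rate, gamma,
  colsample_bytree); the originally searched grid was never published. The
  full product grid (~5 000 points × 10 folds) is far beyond a desk budget,
  so the search is randomized with a configurable iteration count and the
  calibration experiments use a fixed single-point configuration
  (300 trees, depth 6, learning rate 0.1, subsample 0.8) — there the
  question is calibration, not tuning.
- **Importance**: mean |SHAP| per feature over the evaluation rows, computed
  with XGBoost's native TreeSHAP (`pred_contribs=True`); additivity (SHAP
  values sum to the margin prediction) is asserted in tests. Features carry
  coarse family tags (fixation, saccade, yaw, orientation, acceleration,
  cepstral, spectral) for summaries.

## Calibration experiments and problem sizes

The acceptance surface replaces real-data accuracies (not reproducible
without the original recordings) with two synthetic calibrations, run
end-to-end through generation, preprocessing, segmentation, features and
L5O4T evaluation:

- **Null effect**: identical per-condition parameters. Pooled held-out
  accuracy must lie inside the 95 % binomial interval around 0.5. The
  interval uses the number of held-out *recordings* as the count of
  independent units — windows within a recording are strongly correlated,
  so a window-level interval would be anti-conservative.
- **Planted yaw signal**: all contrasts removed except the yaw-oscillation
  amplitude (familiar 15°, unfamiliar 7.5°, i.e. 2×). Pooled held-out
  accuracy must reach 0.85 and a yaw-family feature must hold SHAP rank 1 in
  at least 9 of 10 seeds.

Problem sizes were chosen as the package's own working scale: 10
participants (20 recordings on ~250 m routes with four turn junctions,
roughly 350 windows), 3 held-out participants per condition, 10 seeds in the
test suite and 5 in the acceptance script. Larger cohorts sharpen the
estimates but change nothing structurally; all sizes are function arguments.

## Known limitations

- The generator produces stationary behavior within a recording; real
  wayfinders drift (fatigue, learning within the unfamiliar route).
- Yaw omits the route heading profile and compass wrap-around interacts
  with per-recording mean-centering near ±180°.
- The IMU-based saccade compensation assumes a fixed angular-to-scene
  calibration; real scene cameras have lens distortion and rolling shutter.
- The 10 m arrival radius is a geometric simplification of
  building-footprint decision areas.
- Whether the 10 m/s² rule in the original procedure thresholds the SST
  score or the filtered free acceleration is ambiguous in the source
  description; here it thresholds the filtered free-acceleration magnitude,
  gated by SST peaks, and the choice is recorded rather than silent.
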