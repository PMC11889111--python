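# wayfam

Classifying a pedestrian wayfinder's **spatial familiarity** — does this
person know the route they are walking? — from head and eye movements
recorded in the street: mobile eye-tracking gaze positions (200 Hz), a
head-mounted IMU (tri-axial acceleration, free acceleration, roll/pitch/yaw;
100 Hz after downsampling) and a 1 Hz GNSS track. The package is a complete,
tested re-implementation of that analysis pipeline on synthetic sessions, for
researchers in spatial cognition and wearable-sensor analytics who want to
study, stress-test or extend the method without access to field recordings.

## What it does

1. **Synthetic sessions** (`wayfam.synthetic_data`) — walks along a route
   polyline with gait-band accelerations, slow yaw "looking around"
   scanning, a fixation–saccade renewal process for gaze (log-normal
   fixation durations, gamma saccade amplitudes), GNSS noise, instruction
   -request events and Poisson-placed cap-touch artifact bursts. The
   familiar/unfamiliar contrast enters through four independently
   configurable channels: yaw-oscillation amplitude, acceleration noise,
   fixation dispersion, saccade amplitude.
2. **Preprocessing** (`wayfam.preprocess`) — zero-phase Butterworth low-pass
   on free acceleration, singular-spectrum-transformation (SST) change-point
   scores, classification of the signal into desired/undesired parts at a
   10 m/s² free-acceleration threshold gated by SST peaks, removal of
   undesired intervals from IMU *and* gaze, yaw-extremum time-offset
   refinement, weighted-average repair of flagged GNSS samples and
   projection onto the route, nearest-timestamp IMU downsampling.
3. **Segmentation** (`wayfam.segment`) — *matching-to-action* segments, from
   each instruction request to arrival at the referenced junction, cut into
   non-overlapping 3 s windows.
4. **Features** — per window, 28 gaze descriptors (I-DT fixations at
   dispersion threshold 0.02 normalized units / 100 ms; head-rotation-
   compensated saccade amplitudes; long/short-saccade ratio) and 99 IMU
   descriptors in six families (basic statistics of mean-centered channels,
   50 cepstral coefficients, time-domain measures, fundamental period,
   movement measures, spectral/music measures).
5. **Classification** (`wayfam.model_eval`) — XGBoost with negative
   log-likelihood scoring, 3-SD outlier filtering fit on training rows,
   window-level 80/20 and leave-five-out-for-testing (**L5O4T**) validation
   with repeat draws and average/best/worst reporting, and feature
   importance as mean |SHAP| via XGBoost's native TreeSHAP.

## Worked example

```python
from wayfam import EffectConfig
from wayfam.pipeline import run_study

report = run_study(
    EffectConfig(), n_participants=10, seed=1,
    feature_sets=("gaze", "imu"), schemes=("l5o4t",),
    n_repeats=3, n_holdout_per_condition=3,
)
print(f"windows: {report['n_windows']}  recordings: {report['n_recordings']}")
for fs in ("gaze", "imu"):
    r = report["results"][fs]["l5o4t"]
    print(f"{fs:>4s}  L5O4T avg {100*r['accuracy_avg']:.1f}%  "
          f"best {100*r['accuracy_best']:.1f}%  worst {100*r['accuracy_worst']:.1f}%")
```

prints

```
windows: 349  recordings: 20
gaze  L5O4T avg 90.9%  best 92.5%  worst 89.5%
 imu  L5O4T avg 99.6%  best 100.0%  worst 98.8%
```

— 10 synthetic participants, each walking one familiar and one unfamiliar
route, give 349 three-second decision-phase windows; under the default
condition contrast the classifier separates the conditions almost perfectly
from IMU features alone, with the held-out participants never seen in
training. The top SHAP features in this run are `rel_yaw_min` and
`rel_yaw_max` — yaw dynamics, i.e. head scanning, carry the signal. (The
synthetic contrast is cleaner than real street behavior, so these accuracies
sit above what field recordings yield; the null-effect calibration below
shows they are not an artifact of the pipeline.)

The same steps are scriptable from a shell:

```sh
wayfam simulate --participants 10 --out cohort/ --seed 1
wayfam preprocess --in cohort/ --out clean/
wayfam features --in clean/ --out features.csv
wayfam train --features features.csv --scheme l5o4t --repeats 10 \
             --seed 1 --out report.json
wayfam report --in report.json --plots plots/
```

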