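# scigait

Ankle-IMU gait analysis for the six-minute walk test (6MWT) after
incomplete spinal cord injury (iSCI).

Most iSCI patients who regain ambulation walk with deficits that a
stopwatch-and-tape 6MWT cannot see: asymmetry, stride-to-stride
variability, compensatory circumduction, fatigue-related slowing.  With
one inertial measurement unit strapped above each ankle (tri-axial
accelerometer ±16 g, gyroscope ±2000 °/s, 200 Hz), `scigait` turns a
routine 6MWT into a quantitative gait assessment and two downstream
analyses:

1. **Gait parameter extraction.**  Cadence from the spectrum of the
   sagittal shank angular velocity ω_z; initial/final foot contacts from
   adaptive-threshold peak detection; 3D per-stride ankle trajectories
   by magnetometer-free orientation estimation and zero-velocity-update
   (ZUPT) double integration.  Each trial is summarised by a fixed
   feature vector: for every base parameter X (stride duration, step
   duration, swing phase, double support phase, stride length, width,
   height)

   - mean X̄,
   - cov = σ/X̄ · 100 % (stride-to-stride variability, sample sd),
   - asym = |X̄_L − X̄_R| / (½(X̄_L + X̄_R)) · 100 % (symmetry index),
   - d2r = (X̄ − X̄_ref(v)) / X̄_ref(v) · 100 % (deviation from healthy
     controls interpolated to the same walking speed v),

   plus cyclogram shape metrics (SSD against a healthy reference shape,
   the angular component of the coefficient of correspondence ACC, and
   enclosed area, for the side and top views of the ankle loop),
   movement smoothness (modified spectral arc length of ω_z), and
   fatigue metrics (slope/intercept of linear fits of speed, stride
   length and cadence over the six minutes; speed inconsistency).
   Side-specific parameters are taken from the more impaired side (the
   lower per-leg lower-extremity motor score; right side for controls
   and ties).

2. **Cohort statistics.**  PCA on the standardised feature table with
   cumulative-explained-variance component selection, Ward-dendrogram
   elbow choice of k, k-means gait-cluster discovery, data-driven core
   feature selection (top-5 loadings per PC, Kruskal–Wallis filter,
   Pearson-redundancy pruning, Dunn post-hoc tests), and
   leave-one-subject-out random-forest prediction of whether a patient
   will improve the 6MWT distance by more than the 16.5 m standard
   error of measurement before the next assessment.

Patient recordings are not distributable, so the package ships a
synthetic-data generator (`scigait.synthetic`) that plants known stride
kinematics, cluster structure and improvement effects; every stage is
validated against that ground truth.

## Worked example

```python
import numpy as np
from scigait import (GaitProfile, NoiseModel, TrialMetadata,
                     simulate_trial, process_trial)

profile = GaitProfile(stride_duration_mean=1.1, stride_length_mean=1.2,
                      swing_fraction=0.38, trial_duration=360.0)
noise = NoiseModel(accel_noise_sd=0.1, gyro_noise_sd=0.05, seed=1)
left, right, truth = simulate_trial(profile, noise)

meta = TrialMetadata(subject_id="S01", cohort="SCI",
                     lems_left=20, lems_right=24)   # left more impaired
features, side_params, _ = process_trial(left, right, metadata=meta)
s = features.to_series()
print(f"stride duration {s['stride_duration_mean']:.3f} s "
      f"(cov {s['stride_duration_cov']:.1f} %)")
print(f"stride length   {s['stride_length_mean']:.3f} m")
print(f"swing {s['swing_pct_mean']:.1f} %  "
      f"double support {s['double_support_pct_mean']:.1f} %")
print(f"mean speed      {s['mean_speed']:.3f} m/s")
```

prints (planted values: 1.1 s, 1.2 m, swing 38 %, double support 24 %):

```
stride duration 1.096 s (cov 2.8 %)
stride length   1.202 m
swing 38.1 %  double support 23.7 %
mean speed      1.120 m/s
```

i.e. the pipeline recovers the planted stride duration to well under
10 ms and the stride length to well under 2 % even with realistic
sensor noise.  A thin CLI mirrors the stages:

```sh
scigait simulate trial --seed 1 --out sim/
scigait events sim/trial.h5 --out events.csv
scigait features sim/trial.h5 --out features.csv
scigait cluster cohort_features.csv --out results/
scigait predict longitudinal.csv --feature-set 2 --out cv.json
```

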