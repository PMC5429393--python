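# gazelab

Binocular eye-tracker calibration and gaze-analysis toolkit for vision
science.  Low-cost consumer eye trackers (~55–60 Hz, moderate precision) are
attractive for oculomotor research, but their factory calibration leaves a
spatially structured residual error of several tenths of a degree that varies
over the screen and differs between the two eyes.  `gazelab` implements a
device-agnostic pipeline to measure, model and remove that error, to quantify
gaze data quality, and to analyze the eye movements such devices can record —
saccades, smooth pursuit, vergence and fixation patterns.  A bundled synthetic
eye-tracker simulator with known ground truth makes every stage testable
without hardware or human subjects.

## The method

**Calibration.** Fixation targets from nested layouts (5, 9 or 13 points:
center, corners, cross arms, mid-quadrant diagonals) are presented in random
order for 2 s each.  The first 0.5 s of each dwell — typically contaminated by
compensatory saccades — is discarded, and the gaze position is taken as the
component-wise median of the remaining valid samples.  Targets with error
> 0.5° are flagged for re-measurement.  The per-target error vectors
e(x) = ĝ − g are then interpolated over the screen with a biharmonic radial
basis surface, separately per axis and per eye:

    s(p) = c + Σⱼ wⱼ g(‖p − pⱼ‖),   g(r) = r²(ln r − 1),  g(0) = 0

where the knots pⱼ are the measured gaze medians.  With zero ridge the surface
passes exactly through every observation, so subtracting s(p) evaluated at the
measured position corrects each calibration point exactly; a 12-point test
layout interleaved between the calibration points quantifies the residual
error at held-out locations.  Calibration can be run binocularly or
monocularly per eye, and applied online or offline.

**Quality metrics.** Accuracy (median and IQR of angular error, binned by
target eccentricity — errors are skewed, so quantiles, not means), precision
(SD of fixation samples about their centroid, axes in quadrature),
inter-sample-interval statistics (median ISI → effective sampling rate),
calibration repeatability (Pearson correlation between repeated correction
surfaces sampled over the calibrated area), and paired one-tailed t-tests
across procedures.

**Eye-movement analysis.** Two-point (forward-difference) differentiation for
velocity and acceleration; velocity-threshold saccade detection with
peak-fraction onset/offset refinement; dispersion-based (I-DT) fixation
detection; vergence as the left-minus-right horizontal gaze angle
(convergence positive); pursuit gain as median eye velocity over target
velocity; fixation maps as Gaussian-KDE-smoothed 2D histograms normalized to
unit mass.

## Worked example

```python
import numpy as np
from gazelab import GazeCalibrator, make_layout
from gazelab.simulator import (NoiseModel, default_geometry, make_bias_field,
                               simulate_calibration_session)

geom = default_geometry()                      # 24" 16:9 screen at 800 mm
bias = make_bias_field(seed=3, amplitude_deg=1.0)   # unknown device error
noise = NoiseModel(precision_sd_deg=0.2)

session = simulate_calibration_session(make_layout("13P", geom), bias=bias,
                                       noise=noise, rate_hz=55.0, seed=7,
                                       geometry=geom)
calib = GazeCalibrator(mode="binocular").fit(session)

test = simulate_calibration_session(make_layout("TEST12", geom), bias=bias,
                                    noise=noise, rate_hz=55.0, seed=8,
                                    geometry=geom)
table = calib.run_test(test)
print(table[["uncorrected_deg", "corrected_deg"]].median())
```

prints

```
uncorrected_deg    0.491923
corrected_deg      0.048048
```

i.e. the 13-point biharmonic correction reduces the median angular error at
held-out test targets from ≈0.49° (the raw device error under a 1° smooth
bias field with 0.2° sample noise) to ≈0.05°, an order-of-magnitude
improvement limited only by measurement noise.  The same estimator exposes
`surfaces_` (per-eye correction fields), `retry_targets_` (the 0.5° rule) and
`transform(recording)` for offline correction of arbitrary recordings.

A `gazelab` command-line interface wraps the library for shell use:
`gazelab simulate`, `gazelab info`, `gazelab calibrate`, `gazelab apply`,
`gazelab quality`, `gazelab events`, `gazelab fixmap`.

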