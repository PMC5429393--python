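# Methods

## Coordinate conventions and geometry

Gaze and target positions are expressed in degrees of visual angle with the
origin at the screen center, x positive rightward and y positive upward.
The mapping from metric screen offsets is per-axis gnomonic: a point at
physical offset (dx, dy) mm maps to (atan(dx/D), atan(dy/D)) with D the
perpendicular viewing distance through the screen center.  This convention is
exactly invertible (pixel ↔ degree round trips hold to 1e-9), which matters
because recordings are stored in degrees and are therefore portable across
screen geometries.  The cyclopean eye is assumed on the central perpendicular
(chin-rest viewing); angular distances between screen points are true 3D
angles between gaze rays, computed via `atan2(‖a×b‖, a·b)` for numerical
stability near zero.  Inside a standard ±18° × ±10.5° workspace the 3D angle
differs from the Euclidean distance in degree coordinates by under 1%, but
the 3D angle is unambiguous, so it is used throughout (eccentricity, saccade
amplitudes when a geometry is supplied).

Vergence demand of a fixation at distance d with inter-pupillary distance
`ipd` is `2·atan(ipd/(2d))`.  The IPD is always an explicit parameter — it is
not guessed from population means, since a ±10 mm IPD spread changes the
demand at 1 m by ~0.6°.

## Calibration model

Per eye and axis, the correction surface is an interpolating radial basis
expansion with the 2D biharmonic kernel g(r) = r²(ln r − 1), g(0) = 0, plus a
constant term equal to the mean error.  The weights solve the dense n×n
system G w = e − ē exactly; an optional ridge term (default 0) is exposed for
deliberately smoothed fits on noisy observations.  Only a constant polynomial
term is included; no affine trend is added, because the kernel expansion
itself reproduces smooth trends well inside the target hull (a linear bias
field is recovered at interior held-out points to < 0.05°) and the constant
keeps the system square and strictly interpolating.

The surface is defined as a function of **measured** gaze position: its knots
sit at the measured per-target gaze medians, and correction subtracts the
surface evaluated at each sample's measured position.  This makes the
correction of the calibration observations exact by construction (noiseless
sessions correct to < 1e-6°).  Anchoring the knots at the displayed target
positions instead is available as an option; for errors much smaller than
the surface length-scale the two differ at second order only.

Aggregation uses the component-wise median of valid samples after discarding
the first 500 ms of each 2 s dwell.  The retry rule flags targets whose error
magnitude strictly exceeds 0.5° (ties pass); in binocular mode either eye can
flag a target.  Re-measured targets replace the original observation.
Outside the convex hull of the knots the surface extrapolates smoothly but
evaluations carry an extrapolation flag, since nothing constrains the fit
there.

Layouts are parametric, scaled to the screen's angular workspace: 5P = center
+ corners, 9P adds the edge midpoints, 13P adds mid-quadrant diagonal points
at half the corner offsets (the sets nest), and TEST12 is a 4×3 grid
interleaved between calibration points (every test point is > 0.5° from every
calibration point and inside the 13P hull).  Outermost points sit at 90% of
the workspace half-ranges by default.

## Synthetic data generator

The simulator emulates the class of consumer binocular trackers the toolkit
targets, with all randomness drawn from explicit seeds:

- **Sampling**: nominal 55 Hz (18.2 ms ISI; the observed median sampling time
  of such devices is ≈18 ms against a nominal 60 Hz), Gaussian ISI jitter,
  and per-eye dropout flagged invalid.
- **Systematic error**: a smooth per-eye bias field — K Gaussian bumps with
  random centers, vector amplitudes and widths of 8–16° plus a weak affine
  term, rescaled so its maximum magnitude over the workspace equals the
  declared amplitude (default 1°, the scale of raw consumer-tracker error).
  Bump widths are at least the 13-point inter-target spacing, i.e. the field
  is recoverable at the layout scale; narrower structure would be aliased by
  any point-based calibration.
- **Skewed error**: an optional per-fixation offset with Gamma-distributed
  magnitude and uniform direction reproduces the left-skewed, long-right-tail
  angular error histograms of real devices (a Poisson law on a continuous
  angular variable is ill-defined; a small-shape Gamma is the standard
  continuous analogue).
- **Eye dominance**: the non-dominant eye's bias amplitude is scaled by 1.3
  by default, reflecting its larger mean gaze error.
- **Oculomotor events**: saccades follow a raised-cosine velocity profile
  v(t) = Vp(1 − cos 2πt/T)/2 with Vp = 2A/T — a 10°, 50 ms saccade peaks at
  exactly 400 deg/s, consistent with main-sequence kinematics; pursuit is a
  constant-velocity ramp tracked at a configurable gain after a latency;
  vergence steps approach the disparity exponentially (default time constant
  60–80 ms) and are applied antisymmetrically (±disparity/2) to the two
  eyes' horizontal angles, convergence positive.
- **Compensatory saccades**: calibration dwells optionally begin 1–2° off
  target, settling with a raised-cosine window that reaches exactly zero at
  300 ms.  The window (rather than an exponential) is deliberate: the
  transient is strictly gone before the 500 ms discard, so noiseless
  aggregation is exact, matching the discard rule's intent.
- **Fixation disparity**: in binocular viewing an optional disparity offset
  (default off; 0.2–0.4° when studying mode coupling) shifts the two eyes'
  true gaze by ±d/2.  This is a *behavioral* effect present only binocularly,
  which is what makes monocular-calibration + monocular-test outperform
  binocular-calibration + monocular-test; per-eye device bias alone cannot,
  since both modes would learn it equally.

What the simulator does **not** emulate: pupil-image formation, head movement
inside a track box, blinks with realistic temporal structure, saccadic
under/overshoot dynamics, or drift/tremor within fixations.  Passing tests
therefore demonstrate correctness of the algorithms under the stated error
model, not end-to-end fidelity to any particular physical device.

## Quality metrics

Quantiles use linear interpolation between order statistics (type 7)
throughout.  Accuracy is reported as median/IQR per eccentricity bin because
angular errors are skewed; cohort tables use mean ± SD with a paired
one-tailed t-test against the uncorrected baseline (t = m/(s/√n), df = n−1,
upper tail).  Degenerate cases: all-zero differences return t = 0, p = 0.5
(identical procedures are "no evidence of improvement", not an error); zero
variance with nonzero mean returns ±inf with p ∈ {0, 1}.  Precision is
√(var_x + var_y) with population variances — translation-invariant, linear in
the noise SD, and equal to σ√2 for isotropic per-axis noise σ.  Eccentricity
bins round to 0.1° to merge floating-point-equal radii; the bin structure is
layout- and geometry-dependent by construction.  Repeatability samples each
pair of correction surfaces on a common 25×25 grid restricted to the
intersection of their hulls and reports Pearson's ρ per axis; four
repetitions give C(4,2) = 6 pairwise estimates.

## Event detection

Differentiation is the plain two-point forward difference assigned to the
interval midpoint, applied twice for acceleration; no pre-smoothing by
default (a moving-average filter is available but off).  The saccade detector
thresholds speed at 30 deg/s (50 deg/s in noisy protocols), refines
onset/offset outward to 10% of the event peak, then extends one sample
further on each side: with a forward differentiator the boundary intervals
contain part of the saccade's displacement, and without the extension the
amplitude of a 10° saccade sampled at 55 Hz is underestimated by up to ~0.6°
depending on phase.  Events shorter than 10 ms are discarded.  At 55 Hz the
measurable peak velocity of a 10°/50 ms raised-cosine saccade is biased low
(≈360 deg/s instead of 400) because each velocity sample is an 18 ms average;
the bias falls below 1% at 240 Hz.  Amplitude and duration, not peak
velocity, are the rate-robust recovery metrics.

Fixations use I-DT: a window of at least 100 ms is accepted when
(max−min)_x + (max−min)_y ≤ 1° and grown while it remains so; centroids are
component medians.  Both thresholds are exposed — with per-axis noise σ the
expected dispersion of an n-sample window is ≈4σ per axis, so thresholds
should be ≥ 8σ to avoid splitting long fixations.

Vergence is the difference of horizontal gaze angles (disconjugacy), not a
3D gaze-ray intersection: under chin-rest viewing with screen-plane gaze
coordinates the horizontal-angle difference is the well-posed quantity.  An
optional pre-stimulus baseline window re-zeros the trace to the screen plane.
Pursuit gain is the median two-point eye velocity inside a caller-chosen
closed-loop window divided by target velocity; the median is robust to
catch-up saccade outliers, and because adjacent forward differences share a
sample (negatively correlated noise), its variance is far below the
independent-sample expectation.

Fixation maps evaluate a Gaussian kernel density on a regular grid (default
96×54 over the workspace) and normalize so density × cell area sums to one
exactly; "auto" bandwidth is Silverman's rule per axis, averaged, with a
one-cell floor for degenerate inputs.  The diffusion KDE is a noted possible
extension, not silently approximated.

## Problem sizes and numerical choices

Simulated validation uses 2 s dwells at 55 Hz (~110 samples, ~82 after the
discard), 20-seed cohorts for calibration recovery and 100-seed batches for
kinematic recovery; large-n estimator checks use 1e5 samples.  These sizes
put Monte-Carlo error well below the tolerances asserted (e.g. SE of a median
over 82 samples at σ = 0.2° is ≈0.03°).  Linear systems are solved with
`numpy.linalg.solve` (13-point systems are well-conditioned; duplicate knots
are rejected explicitly).  Convex-hull membership uses Delaunay
triangulation; layouts with fewer than three non-collinear points have no
hull and all queries are flagged as extrapolation.  Timestamps are float
milliseconds; ISI jitter is clipped at 0.05 ms to keep them strictly
increasing.

## Known limitations

- The correction surface is only constrained inside the target hull;
  extrapolated corrections are flagged but not suppressed.
- Exact interpolation (ridge 0) transfers per-target measurement noise into
  the surface; with the median of ~80 samples this noise is ≈0.03°, but for
  short dwells a positive ridge is advisable.
- The I-DT detector is greedy and order-dependent at window boundaries.
- Saccade metrics at 55 Hz carry the sampling biases described above; the
  toolkit reports what a two-point differentiator can measure, by design.
- Trial-aligned analyses align to target onset (not movement onset); latency
  estimates are therefore quantized at the ISI.
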