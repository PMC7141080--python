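# Methods

## Gaze mapping model

The mapping from pupil center $(u,v)$ (eye-camera px) to gaze $(x,y)$
(world-camera px) is a pair of full bivariate quadratics over the basis
$(1, u, v, uv, u^2, v^2)$ — second order with the first-order cross term,
and nothing higher: with marker-sweep calibrations the extra degrees of
freedom of higher orders degrade interpolation more than they help. Both
surfaces are solved in one SVD least-squares problem. Pupil coordinates are
standardized (zero mean, unit variance per axis) before building the design
matrix; this is purely a conditioning measure — predictions agree with the
unstandardized fit to well below 1e-9 px on well-conditioned data, which the
test suite checks. A fit is refused (`DegenerateGeometry`) when the design
matrix is rank-deficient; the error names the basis direction the pupil
geometry failed to excite (e.g. collinear pupils leave `u^2` unidentified).

Assumptions: one eye, no corneal-reflection compensation — the wearer's head
is free and the marker is the anchor; the stimulus plane is flat and at a
known distance; pupil and marker streams are synchronized to within one
frame (pairing tolerance 9 ms ≈ one 114 Hz frame, nearest timestamp, ties
to the later sample).

## Residual correction

At each calibration pair the fitted mapping misses the marker by the
residual $v_i$. Those vectors are Shepard-interpolated to any query $p$ with
weights $d_i^{-r}$ (default $r=2$; distances in world px). Weights are
rescaled by the nearest distance before powering so the interpolation stays
finite arbitrarily close to a node; at $d_i = 0$ the coincident node's
vector is returned (mean, if several coincide) — the limit value of the
interpolant. The corrected estimate is $p + v_p$.

The time-windowed variant first finds the node $N_p$ spatially nearest to
$p$ (ties: earlier timestamp) and restricts the sum to nodes within
$\pm T$ ms of $N_p$'s timestamp, window closed on both sides, default
$T = 200$ ms. On a continuous calibration sweep, nodes close in time are
close in space *and* share the same slowly varying error state, so the
window removes the cross-talk from spatially near but temporally distant
nodes (e.g. the second pass of a spiral). As $T$ grows past the session
span the variant reduces exactly to plain IDW.

Interpretation note: because the IDW weights form a convex combination, the
correction at any point lies in the convex hull of the selected $v_i$; the
error map built from $|v_p|$ is therefore bounded by $\max_i |v_i|$ and
continuous between nodes.

## Pupil and marker detection

Pupil: the threshold is the lowest smoothed-histogram spike plus a fixed
offset of 15 intensity levels (dark-pupil heuristic); a 5×5 morphological
closing fills glint holes; the largest dark component (≥ 100 px², else
`NoPupilFound`) is traced at sub-pixel resolution and an ellipse is fitted
algebraically to the contour. The reported center is the ellipse center. A
frame whose dark mask covers more than half the image is rejected — the
dark-pupil premise is a minority dark region. The uncertainty field inside
the contour is $1 - \mathrm{DT}/\max \mathrm{DT}$ with DT the Euclidean
distance to the contour: 1 on the boundary, 0 at the deepest interior point.
The polarity is a documented convention: 0 marks the most plausible center
location, 1 the least.

Marker: the frame is binarized at the midpoint of its dynamic range (robust
when the marker covers a tiny fraction of the frame, where Otsu collapses),
and candidates are dark components whose filled hole contains both white
pixels and further dark pixels — the black ring / white ring / black disk
nesting. The three regions' centroids must agree within 10 % of the outer
radius; confidence is one minus the worst pairwise disagreement over that
radius. The central white cross is ignored: the inner centroid is taken
over all dark pixels inside the hole, which the cross merely partitions.
More than one candidate above confidence 0.8 raises `AmbiguousMarker`
rather than guessing. The synthetic renderer uses 3:2:1 ring radii — a
convention, as is the choice of the innermost disk as the measured center.

## Synthetic sessions

The generator emulates a 114 Hz stream over a 1920×1080 world frame for up
to 12 s. Marker trajectories: a 3×3 grid (15 % margins, equal dwell), one
constant-speed lap of a rectangle (smooth pursuit), and an inward-then-
outward two-turn spiral standing in for the marker's apparent motion under
head rotation. Markers are exact stimulus ground truth; the true pupil
position is the Newton-inverted image of the marker under a fixed
ground-truth quadratic (dominantly affine across a ±150×±110 px pupil
working range, with quadratic curvature of a few tens of world px at the
corners; inversion residual < 1e-12 px).

Measurement noise enters on the pupil only, in two parts scaled by one knob
`noise_sd_px` (default 1 px, an artifact choice — detector precision at
this image scale):

* white jitter of sd `noise_sd_px` per frame — pupil-detection precision;
* slow drift: a Gaussian process with 0.5 s correlation time and RMS
  `2 × noise_sd_px` — the temporally correlated error of real recordings
  (headset slippage, pursuit lag, residual head-movement parallax).

The drift is the component residual-based correction can recover; with
purely white noise and a truth inside the fitted family, the calibration
residuals are themselves white and interpolating them cannot beat the raw
fit — a session model without correlated error would make any correction
method pointless by construction. Both components vanish at
`noise_sd_px = 0`, so noiseless sessions admit exact-recovery tests
(evaluation MAE ≤ 1e-6 px on any trajectory of rank-6 geometry). An
optional projective `distortion` takes the truth outside the quadratic
family to exercise model mismatch, including the fold-over of projected
contours outside the calibration region.

What passing tests on these sessions do **not** show: robustness to
blinks/occlusions, saccades and pursuit latency, corneal refraction,
non-planar stimulus surfaces, or real camera distortion — none of which the
generator emulates.

## Units and evaluation

Errors are Euclidean norms on the world plane, averaged per method over the
evaluation half of the session (uniform random split, seeded; the
calibration side must keep ≥ 6 pairs). Conversion to centimetres uses
`px_per_cm` (default 37.0 ≈ a 1920-px-wide, 51.7 cm screen — the 24-inch
reference geometry; it is a required input, not derivable from the data).
Conversion to degrees uses $\theta = \arctan(e_\text{cm}/D)$ with $D$ the
viewing distance (default 75 cm); each per-point error is converted before
averaging. This arctan form reproduces the internally consistent published
cm↔degree pairs to print precision; two published cells are arithmetically
inconsistent with their own cm values and are treated as typos. Sessions
are labelled short (< 6 s) or long (6–12 s); beyond 12 s a calibration is
excluded.

## Numerical choices and problem sizes

* Rank test: smallest singular value ≤ `s_max · max(m,6) · eps · 1e3`.
* Duplicate-row cleansing compares all four coordinates at 6-decimal stored
  precision, keeps the first occurrence, and is idempotent.
* Maps raster: world frame downsampled by an integer factor (default 4);
  Gaussian kernels (sd 20 world px ≈ 1 % of width) are normalized to unit
  mass per sample, polygon kernels are left unnormalized so bigger — more
  uncertain — pupils deposit more spread; that asymmetry is the point of
  the pupil-shaped kernel. Bump rendering is Lambertian with
  central-difference normals, min–max scaled; a constant field renders
  mid-gray.
* Test and acceptance problem sizes — 2–5 s sessions (228–570 pairs), 50
  random eye renderings, 100 random IDW node sets — are chosen as the
  smallest sizes at which the checked properties are non-trivial; all
  suites run in seconds on one core.

## Known limitations

Pupil detection assumes the dark-pupil regime and a single pupil-sized dark
blob; heavy eyelash occlusion or off-axis glints larger than the closing
kernel will bias the ellipse. Marker detection assumes exactly one marker
and a light background. The quadratic mapping extrapolates poorly outside
the calibration hull — predictions there are flagged, and projected
contours can fold (detected and reported). The windowed correction inherits
IDW's behaviour of collapsing to a single node's vector very close to a
node, which transfers that node's noise; it pays off when error is
temporally correlated, and does nothing for purely white error.
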