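# Methods

This note documents the models, parameter choices and numerical
decisions behind `matmotion`, and what the synthetic validation does and
does not demonstrate.

## Coordinate frames and conventions

* **Mat / reference frame (REF).** Origin at the mat corner carrying the
  reference IMU; *x* across the mat (0.47 m), *y* along it (0.80 m),
  *z* up. Pixel (i, j) of an H × W pressure image has its centre at
  `y = (i+0.5)·0.80/H`, `x = (j+0.5)·0.47/W`.
* **Earth frame (E).** *z* opposite gravity, *y* along the horizontal
  component of the magnetic field, *x* east. In the simulator E and REF
  coincide; in general the REF unit's estimated orientation maps one
  into the other.
* **Trunk frame (T).** *x* medial–lateral (toward the baby's left),
  *y* caudal–cranial, *z* dorsal–ventral. Supine on the mat, T ≈ REF.
* **Segment frames (UA, FA).** *y* proximal→distal; the elbow hinge is
  the segment *z* axis.
* Quaternions are Hamilton, scalar-first; `q` maps body-frame vectors
  into the parent frame. Angles on the mat are measured from the long
  (*y*) axis, positive toward +*x*, wrapped to (−π/2, π/2] because an
  imprint axis is undirected.

## Pressure-image stack

Per frame: bias-matrix subtraction (clamped at zero) → noise floor
(default 2 device units) → 8-connected component labelling
(`scipy.ndimage.label`) → artefact filter (area ≥ 3 px AND total load
≥ 10 units; kills single-pixel cross-talk while a 3-pixel hand imprint
survives) → piecewise-linear upsampling ×3 on a Delaunay triangulation
of pixel centres (55×32 → 165×96; the interpolation weights are
precomputed once, so each frame is a sparse mat-vec; values at raw pixel
centres are preserved exactly, fine pixels outside the hull of raw
centres copy their nearest raw pixel).

The **COP** is the load-weighted centroid of pixel centres. The **trunk
imprint** is the union of labelled objects whose centroid lies within
ρ = 12 cm of the COP (newborn trunk half-length scale); the object
nearest the COP is always included. Its **orientation** is
`½·atan2(2µ11, µ20 − µ02)` of load-weighted central moments after a
1st–99th percentile contrast stretch; an isotropic imprint has no
principal axis and reports NaN with zero trust.

**Trust model.** The stated criteria (imprint load, imprint length, COP
centrality) are combined as a product of unit-clipped linear ramps:
`trust = clip(load/500) · clip(length/0.10 m) · clip(1 − d/0.30 m)`,
where length is the 4σ major-axis length of the moment ellipse and d the
distance of the imprint centroid from the mat centre. This is the
simplest model that is monotone in each stated criterion; orientations
with trust ≥ 0.5 are treated as reliable. The reference constants are
scaled so a centred newborn trunk imprint saturates the first two ramps.

**Shoulders.** Placed symmetrically about the trunk axis at a pre-set
cranial offset (10 cm from the COP) and half-separation (6 cm), at 5 cm
height. The trunk IMU supplies the cranial disambiguation and the roll
angle; rolling lowers the down-going shoulder by `s·sin(roll)`, raises
the other, and shrinks the projected separation by `cos(roll)` (rigid
doll-model projection). When the cranial half of the imprint shows two
load peaks with prominence ≥ 20 % of the band maximum (double-histogram
analysis), the peak positions override the pre-set lateral offsets.

**Head.** Candidate objects cranial of the shoulder line within a 45°
cone; when head and trunk merge into one object the axial load profile
is split at its valley (the neck) and the cranial part's centroid is
used. A candidate implying head speed above 0.5 m/s w.r.t. the tracked
position is rejected in favour of the previous position (human head
dynamics are limited; the exact published search algorithm is not
reconstructable, so this cone-plus-tracking scheme is a declared
stand-in with the same inputs and outputs).

## Attitude UKF

Error-state quaternion UKF (Merwe sigma points, α = 10⁻², β = 2, κ = 0)
with state = 3-D attitude error about the reference quaternion + 3-D
gyro bias. Prediction integrates the bias-corrected gyro with the
body-frame exponential map; updates use the normalized accelerometer
(gravity direction) and magnetometer (field direction) with per-axis
noise 0.05 m/s² and 0.01 unit-field. Defaults: gyro white noise
0.005 rad/s per sample, bias random walk 10⁻⁵ rad/s per step, P₀ =
(10°)² attitude, (0.01 rad/s)² bias. The magnetic dip angle is
self-calibrated from the first second of data (mean of â·m̂), so no site
survey is needed.

Three robustness devices, all off the critical path in normal operation:

* **Dynamic-motion guard.** When ‖a‖ deviates from 1 g by more than
  0.5 m/s², the accelerometer update's noise is inflated ×100 so linear
  acceleration cannot corrupt the attitude.
* **Acquisition watchdog.** If, on quasi-static samples (guard
  inactive), the estimate disagrees with the analytic
  accelerometer/magnetometer (TRIAD) attitude by > 10° persistently
  (leaky count of 6 checks at a 5-sample stride), the attitude is
  re-acquired from the analytic fix and its covariance reset. This makes
  convergence from an arbitrary initialization deterministic; it cannot
  fire during genuine movement because the guard gates the check.
* **Bias settling window.** Bias updates are frozen for the first 2 s so
  a large initial attitude transient cannot push a spurious value into
  the bias state (the classic slow bias–yaw equilibrium that otherwise
  holds a degree-level yaw error for many seconds).

By default the filter initializes from the TRIAD solution of the first
sample, so the watchdog matters only for deliberately wrong
initializations. With gyro ≡ 0 the filter converges to the TRIAD
solution (static equivalence, tested).

**Trunk fusion.** The trunk unit's yaw about the mat normal is rotated
so the projected caudal–cranial axis matches the imprint angle whenever
trust ≥ 0.5 (the imprint angle's π-ambiguity is resolved toward the
current estimate); the applied offset is remembered and held during
low-trust stretches. Roll and pitch are never modified, and the
correction is idempotent at full trust.

## Kinematics and metrics

Forward kinematics and the placement-error chord law are implemented
exactly as stated in the model section of the README; rigid-link norms
are conserved to 1e-12 and the chord law is verified against the
FK-difference oracle to 1e-9 in the tests. The elbow angle is the angle
between the two segments' distal axes.

Numerical choices in the metric suite:

* Filtering: 2nd-order Butterworth, forward–backward (zero phase),
  6 Hz cutoff for velocities and positions.
* Acceleration-to-velocity integration: 0.2–6 Hz band-pass before the
  trapezoid, matching high-pass after it; drift-free by construction.
* Movement segmentation (the published interval count has no stated
  rule): hysteresis on the filtered speed, on at 0.05 m/s, off at
  0.02 m/s, minimum duration 0.3 s — scaled to ≈13 cm/s movements.
* SAL: spectrum zero-padded to 0.01 Hz resolution, band [0, 10 Hz]
  (above the 6 Hz filter band); amplitude-invariant by construction.
* Workspace: least-squares sphere radius about the shoulder is the mean
  point norm (fixed-centre model); single-IMU placements use the fixed
  radius l_UA + l_FA. Directions are mapped through the Lambert
  azimuthal equal-area projection about the ventral pole, so planar
  alpha-shape area equals spherical area exactly; normalizers are the
  frontal hemisphere area 2πr² and volume ⅔πr³.
* Alpha shapes are alpha complexes on scipy Delaunay triangulations
  (simplices kept when circumradius ≤ α). The sampling-density rule
  α = 2× median nearest-neighbour spacing degenerates on trajectory
  data, which samples the workspace along 1-D arcs: with it the
  "envelope" collapses to slivers along the arcs. For envelope
  estimation α is therefore floored at 0.15× the cloud diameter, which
  connects arcs at the movement scale while leaving dense samplings
  (where the rule is adequate) unchanged.

## Simulator: what it emulates, and what it does not

The doll model is preterm-newborn scale: trunk ellipse 24 × 12 cm, head
10 × 9 cm, l_UA = l_FA = 7 cm, shoulder half-separation 6 cm, trunk
centre 5 cm above the mat. Motion scripts compose REST, TRUNK_ROLL
(minimum-jerk roll about the caudal–cranial axis) and REACH primitives
(minimum-jerk hand paths, two-link inverse kinematics with the elbow
plane spanned by the reach direction and the trunk dorsal–ventral axis).
The default session profile is 50 reaches of 9.1 cm in 0.7 s each
(mean movement speed 13 cm/s) plus four roll segments to ±40°, in 60 s —
a movement density matching published session statistics for this kind
of recording (session-average hand speed of a few cm/s). IMU synthesis:
body rates by the 100 Hz logarithmic-map increment, specific force from
double-differentiated sensor positions, field direction at 60° dip;
white noise plus a random-walk gyro bias. Pressure frames render trunk
and head as elliptical paraboloid load patches; rolling narrows the
trunk patch by cos(roll), shifts it toward the down-going side and
conserves total load; a smooth synthetic per-module bias field and white
pixel noise are added. All randomness flows from one seed.

Not emulated: mattress compliance and soft-tissue deformation, skin
motion of the sensor mounts, magnetic disturbances, marker occlusion.
Passing the synthetic validation therefore demonstrates the correctness
and internal consistency of the processing chain under realistic sensor
noise — not robustness to soft-tissue artefact or ferromagnetic
environments, which only real recordings can probe.

## Validation problem sizes

The test suite validates each stage against independent oracles
(flood-fill labelling, closed-form quadrature, analytic profiles,
rigid-body projections) and runs end-to-end checks on two 60 s sessions;
the Monte-Carlo filter checks use 100 runs (static) and 100 seeds
(dynamic, 6 s scripts). The acceptance script uses twenty 60 s sessions,
both arms each — sizes chosen so the whole validation completes in
minutes on one core while keeping seed-averaged statistics stable.

## Known limitations

* The single-IMU placements inherit the full chord-law error at flexed
  elbows; this is a property of the sensor reduction, not of the code.
* The trust model and the shoulder/head detectors use declared, simple
  parametrizations; their constants are anthropometric defaults, not
  fitted values.
* Yaw accuracy is anchored to the magnetometer; hard/soft-iron
  calibration is out of scope.
* The pressure mattress is modelled as one contiguous 55 × 32 grid; the
  physical two-mattress seam is not represented.
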