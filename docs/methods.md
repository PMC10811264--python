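# Methods

This note documents the models, the defaults and the design choices made
where the design was genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Frames, conventions and units

All geometry uses a right-handed frame with x vehicle-forward, y to the
occupant's right, z vertically **down** (SAE-style).  Consequences worth
spelling out: positive rotation about y is nose-up (extension), so head
flexion is a rotation about −y; positive rotation about z is right axial
rotation; positive rotation about x is right lateral bending.  Angles are
radians everywhere inside the library (degrees only in CSV columns whose
names say so); controller time is milliseconds, so `Kp` [1/rad], `Ki`
[1/(rad·ms)], `Kd` [ms/rad]; plant time is seconds.

## Rotation algebra

`rotation_matrix_zyx` composes elemental rotations around z, then y, then
x.  The default reading is intrinsic z–y′–x″, i.e. the matrix product
`Rz·Ry·Rx`; the extrinsic reading (`Rx·Ry·Rz`) is a keyword switch because
descriptions of this construction in the controller literature often do
not pin the convention down, and at the small combined angles of vehicle
maneuvers the two nearly coincide.

Axis–angle extraction uses the trace formula for the angle and the skew
part of R for the axis.  Two degenerate regimes are handled explicitly:

* θ < 1e−9 rad — the axis is undefined; the documented default (0, 0, 1)
  is returned with a `degenerate` flag, and the controller emits **zero
  directional drive** in that state.  This prevents NaN propagation at
  maneuver start, when the head sits exactly at its reference.
* θ near π — the sine-based formula loses precision; the axis is taken
  from the dominant-diagonal column of `(R + I)/2`, with the sign fixed
  from the skew part where it is resolvable (at exactly π the sign is
  genuinely arbitrary).

Both regimes, and the generic path, are verified against quaternion,
eigendecomposition and trace-formula oracles and a 1,000-sample Rodrigues
round trip at 1e−10.

## Error signals

The **translational** error is the angle between the current and reference
T1→head-CoG links, both expressed in a frame that follows T1 in yaw; its
direction is the azimuth of the horizontal head displacement relative to
the reference link (0 = forward, +π/2 = right).  The **rotational** error
is the axis–angle of `R_refᵀ·R_cur`.  The axis maps onto the STP grid as
`bend_azimuth = atan2(v_x, −v_y)` and `axial_component = v_z`: a pure
flexion deviation (axis (0, −1, 0)) queries azimuth 0, right lateral
bending (axis (1, 0, 0)) queries +π/2, right axial rotation contributes
positive axial component.  STPs describe muscles *returning* the head from
a deviation, so the deviation direction itself is the query.

The load-sharing direction is evaluated from the **undelayed** kinematics
while the error magnitude is delayed by τ (a `delayed_direction` switch
selects the alternative reading); published descriptions leave this open,
and the undelayed choice avoids querying a direction the head has already
left.

## The controller chain

Delay: linear interpolation in a uniformly sampled error history;
pre-history error (t < τ) is 0, consistent with controllers initializing
from rest during gravity settling.  PID: parallel form, trapezoidal
integral, backward-difference derivative.  Negative responses clamp to
zero — muscles pull only; antagonist recruitment is carried entirely by
the direction query, since the chain emits one activity level common to
all muscles.  Saturation clamps at 1 and accumulates the saturated
duration for the tuning constraint.  Distribution:
`min(1, u·w_i + b_i)` with the baseline added **before** the cap
(cap-last); whether published chains cap before or after adding baseline
is unstated, so the choice is documented rather than asserted.  The
baseline is `baseline_scale` × the per-channel minimum of its normalized
pattern, present for the whole run including settling.

Activation dynamics are two cascaded first-order stages (neural
excitation, then active state), advanced with the exponential-Euler update
`X += (1 − e^{−dt/τ})(input − X)`, which is unconditionally stable and
maps [0, 1] inputs to [0, 1] states; a guard still rejects
dt > min(τ)/2.  The delay and the two time constants are **library
defaults** (τ = 30 ms, τ_e = 30 ms, τ_a = 15 ms), in the range used by
published active neck models but not measured constants of this package;
every results header records the values used.

## Spatial tuning patterns

The 26-direction grid stores bend azimuths as integers 0–7 (×45°) to keep
dictionary keys exact.  Source merging selects, per (group, direction),
the single highest-priority record — dynamic+MVIC, then dynamic with
within-experiment-peak normalization, then isometric — with ties broken
on experiment id for determinism, and falls back to a substitute group
with similar function when a group is absent everywhere; provenance is
retained per cell.  Mirroring reflects the azimuth about the sagittal
plane and swaps the axial levels.  Per-direction normalization divides by
the maximum over all groups and both sides, making the per-direction
maximum exactly 1; it is idempotent, scale-invariant and commutes with
mirroring (all tested).

Directional lookup is this package's choice (the grid itself prescribes no
interpolant): periodic-linear in azimuth between adjacent 45° nodes, and
piecewise-linear in |axial component| — no-axial level at 0, signed axial
level at the configurable knot (default 0.5), signed pure-axial entry at
1.  All outputs are convex combinations of stored weights, hence bounded.
Whether and how the pure-axial entries should interact with bend
interpolation at high axial components is unspecified upstream; the knot
is config, not asserted behavior.

The default registry defines 11 muscle groups with anatomically motivated
corrective azimuths (extensors around 0°, right-lateral muscles around
90°, flexors around 180°, SCM and splenius with axial capability) and
literature-scale per-side maximum forces.  Group membership, substitutes
(e.g. trapezius → semispinalis capitis) and geometry are **this
package's** choices.

## Surrogate plant

One rigid head (4.5 kg, inertia diag(0.022, 0.025, 0.015) kg·m²) coupled
to prescribed-motion T1: a translational spring–damper acting at the
atlanto-occipital joint point (2 cm posterior, 12 cm below the CoG), a
rotational spring–damper on orientation, gravity, and 22 point-to-point
muscle elements (11 groups × 2 sides) pulling from skull attachments on a
5 cm ring toward caudal origins at T1 level, with tangential offsets for
the axial correctors.  Translational stiffness is anisotropic —
(2000, 2000, 50000) N/m — because the neck is far stiffer in axial
compression than in shear; without that the muscles' vertical force
components drag the head down unphysically.  Rotational stiffness
(25 N·m/rad) deliberately exceeds the gravitational destabilizing
stiffness m·g·|z-lever| ≈ 5.3 N·m/rad so the passive plant is stable,
with damping chosen near critical.  These constants were set once, during
plant construction, to yield a stable, human-scale surrogate; they are
plant parameters of this package, not measurements.

Integration is semi-implicit Euler at dt = 1 ms (velocity update, then
position; rotation via the exponential map), which is stable for the
stiff passive elements at this scale; halving dt changes peak
displacements by far less than 1 % (tested).  The simulation runs in an
inertial frame: T1 follows the double-integrated vehicle pulse through a
first-order seat-compliance filter (τ = 50 ms, pass-through at 0) standing
in for the unmodelled seat/torso path.  Phases: gravity settling with T1
stationary (default 250 ms; the controller reference is captured at its
end), then the loading phase (defaults 2250 ms braking, 1450 ms lane
change).  Divergence (non-finite state or head rotation beyond π/2)
raises an error naming the first offending step.

Pulse shapes are the package's choice where only peak and duration are
prescribed: braking is a −x trapezoid with haversine onset and release
(ramp fraction 0.15); lane change is two opposite haversine lobes (+y
then −y), giving exactly one sign reversal and zero net velocity change.

A closed-form statics oracle validates the plant: with the controller off,
equilibrium pitch satisfies `m·g·(c_x cosθ + c_z sinθ) = K_r·θ` (torque
balance about the CoG with the spring force equal to −m·g·ẑ), and the
simulated settling angle matches its Brent-solved root within 2 %.

## Gain tuning

The curve-mapping discrepancy normalizes both curves by the reference
peak magnitude and the common duration, traces them as polylines in the
normalized (t, y) plane, resamples each at 200 equal fractions of its own
arc length, and averages the pointwise Euclidean offsets.  It is zero iff
the curves coincide and is anchored on the reference (not symmetric).  A
plain RMS-after-resampling metric is exposed for sensitivity checks.  The
proprietary curve-mapping implementation used in commercial optimizers is
not reproduced; this is a documented stand-in with the same role.

The activity constraint returns the maximum of the clamped PID response,
or, at/above the 0.99 ceiling, the ceiling plus the saturated duration in
seconds (scale factor 1.0/s, config) — strictly increasing in saturation
time so the optimizer can order saturated designs.  Whether the published
constraint applied to the pre-dynamics PID signal or the post-dynamics
activation is ambiguous; pre-dynamics is the default, switchable.

SRSM: per iteration, a 200-point Latin-hypercube pool in the current
region, greedy D-optimal selection of 7 designs (determinant of the
linear-model information matrix; the starting design is forced into
iteration 1 so at least one feasible design exists by construction),
linear least-squares metamodels for the scalarized objective and the
constraint, and a linear program minimizing the metamodel objective over
the region subject to the constraint.  The region pans to the predicted
optimum (clipped to the global bounds) and zooms by 0.6 per iteration
(config; zoom 1 degenerates to repeated single-stage RSM, kept as a
regression baseline).  Termination: relative design change and objective
change both below 0.01, or 10 iterations.  Tolerances are interpreted as
relative (the published setup does not say).  Multi-objective handling is
equal-weight scalarization of the 2 or 4 objectives — the aggregation
rule is unstated upstream, and a scalar keeps the optimizer simple; the
weights are config.  The reported design is always the best *simulated*
feasible one, or the run is flagged "constraint violated at optimum".

Default design space: Kp 0.1 ∈ [0, 2], Ki 1e−6 ∈ [0, 0.1], Kd 100 ∈
[0, 1000].  The Ki ceiling is derivable at run time as the largest
theoretical Ziegler–Nichols Ki (`Kp²/4Kd`) across the published reference
controllers, rounded up to the nearest order of magnitude.

## Rating

The per-channel score is `0.5·corridor + 0.5·(0.5·shape + 0.25·size +
0.25·phase)`.  Corridor: per-sample 1 inside the inner band, 0 outside
the outer, linear between, time-averaged; bands default to 1 and 2
reference SDs (a peak-fraction mode exists for references without SD).
Shape: peak normalized cross-correlation over shifts up to 20 % of the
window; size: ratio of absolute areas; phase: the best shift mapped
linearly to [0, 1].  The structure follows the published corridor +
correlation rating scheme, but the constants of the proprietary
implementation are unavailable: scores are comparable in structure, not
numerically, to it, and every constant is config.  Rating thresholds
default to 0.94/0.80/0.58 (excellent/good/fair cuts, boundary to the
higher label) and are likewise config.

Composites weight channel scores by the absolute reference peak; the
overall score gives translations and rotations equal value.  Whether the
upstream weighting used peak or peak-to-peak magnitude is unstated;
absolute peak is used.  Muscle-activity similarity compares the
time-averaged activation over a window against mean ± 1 SD with inclusive
bounds (a 1e−9 relative epsilon keeps float accumulation from flipping an
exact boundary case).

## Fixtures

The STP fixture emulates three source experiments: a dynamic
MVIC-normalized perturbation table covering only the horizontal-plane
directions for 8 of the 11 groups, and dynamic and isometric tables
normalized to the within-experiment peak covering the full grid — so
priority selection, gap filling and substitution are all exercised.
Activities are cosine-tuned in azimuth about each group's corrective
direction, Gaussian in axial level, with additive Gaussian noise
(sd 0.05) and deterministic per seed.  The corridor fixture produces
smoothstep braking corridors (default peaks 0.15 m forward, −0.25 rad
pitch) and biphasic lane-change corridors (−0.05 m lateral, single sign
reversal), with SD bands 20 % of |mean| plus a 5 mm floor.  What the
fixtures do **not** emulate: inter-subject variability structure, sensor
noise spectra, protraction/retraction, and any numeric agreement with
real volunteer corridors — passing tests demonstrate the pipeline's
mechanics and invariants, not bio-fidelity against humans.

## Problem sizes

The default suite simulates at dt = 1 ms: braking 2.5 s, lane change
1.7 s total.  The gain-recovery harness runs the tuner for 10 iterations
× 7 designs with two maneuvers per design (braking 9 m/s²/2 s, lane
change 6 m/s²/2 s), recovering reference trajectories generated by known
gains; recovery is judged by the curve-mapping distance of the retuned
trajectories (well below the untuned baseline) rather than exact gain
equality, since the objective is deliberately flat near its optimum —
the same insensitivity the published tuning reports.

## Known limitations

* The surrogate plant is a single rigid body; no distributed cervical
  spine, no seat/belt, no injury metrics.  Quantitative agreement with
  finite-element human body models or volunteers is out of scope.
* The 11-group registry (membership, substitutes, forces, geometry) is a
  documented package choice, not an anatomical dataset.
* The curve-mapping and rating implementations are structural stand-ins
  for proprietary tools; scores and distances are internally consistent
  but not interchangeable with those tools' outputs.
* The rotational controller ignores pure protraction/retraction, which
  produces no head rotation.
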