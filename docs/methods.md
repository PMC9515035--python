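# Methods

This note documents the models, conventions and numerical choices behind
spheretrack: what the tracker computes, what the synthetic camera emulates,
which parameters matter, and where the design was genuinely open.

## Coordinate conventions

All lengths are millimetres, angles at the API surface are degrees, and
transforms use the column-vector homogeneous convention (`A @ B` applies `B`
first).  Euler angles are intrinsic Z-Y-X (yaw–pitch–roll); at pitch = ±90°
the decomposition is degenerate, the yaw component absorbs the free angle, and
the result carries a `gimbal_lock` flag.  This order is a common robotics /
image-guided-therapy convention; it is a package choice, and rotation-error
magnitudes are reported as the Euclidean norm of the Euler triple, so any
consumer comparing against another convention should convert explicitly.

Pixels are 0-based with centers at integer coordinates, `p = (x, y)` =
(column, row).  Depth is *range along the unit ray*, not z-depth: the
back-projection multiplies the raw depth value by a unit direction vector, so
`‖backproject(p, d)‖ = d` for every pixel.  A depth value of 0 encodes an
invalid pixel.  The world frame is placed at the device pose at the start of a
sequence; the simulated headset is static, so `world_from_left` is constant
(and exact — see Limitations).

## The tracking cycle

Per frame: detect blobs in the AB image → sample depth at each blob center →
back-project and chain into the world frame → correct surface points to
sphere centers → identify correspondences → (optionally) Kalman-filter each
center → register the marker.  Frames that fail any stage produce a gap and a
diagnostic record, never a fabricated pose.  The cycle is deterministic.

**Blob detection.**  Default threshold is `median + 0.35·(max − median)` of
the AB image.  Otsu thresholding (available via `BlobParams.use_otsu`) is
deliberately not the default: sphere blobs cover ~0.02 % of the image, a
foreground fraction at which Otsu's between-class criterion is unreliable.
Components are kept when their area lies in [4, 2000] px² and their
circularity `4πA/P² ≥ 0.6` (rejects streak-like reflections).  The subpixel
center is a background-subtracted intensity-weighted centroid over a window of
±(4.6·r_c + 2) px around each component (r_c = half the bounding-box size,
≈ 1.45 σ of a Gaussian blob at the default threshold, so the window spans
≈ 6.7 σ); pixels belonging to other components are masked out.  The wide
window matters: for a radially symmetric blob profile the grid-sampled
centroid is exact up to the mass truncated outside the window, so ±6.7 σ keeps
the zero-noise centroid error below ~1e-7 px.

**Ray directions at subpixel centers.**  When the lookup table carries its
pinhole parameters, the unit ray at a continuous pixel position is evaluated
analytically — the exact interpolation of the model that generated the table.
Bilinear interpolation of table entries (plus renormalization) is the fallback
for tables without a model and agrees with the analytic ray to ~1e-4; the
analytic path is what makes the zero-noise pipeline exactly invertible.
Depth at the subpixel center is sampled bilinearly, ignoring invalid (0)
neighbours; if all four neighbours are invalid the observation is dropped for
that frame (the filter then runs predict-only).

**Surface-to-center correction.**  The measured point lies on the sphere
surface; the center estimate adds `r_s` along the camera→surface direction.
This is exact precisely when the ray passes through the sphere center, i.e.
at the blob center; it is the reason the tracker only ever samples depth
there.  The invariant `‖center − cam‖ − ‖surface − cam‖ = r_s` holds to
1e-6 mm for every observation and is asserted in the tests.

**Correspondence.**  The marker's pairwise center distances are unique (the
shipped default: minimum distance 61.2 mm, all pairwise-distance gaps
≥ 15 mm), so assignment is by distance pattern: all injective assignments of
`k = min(n_candidates, 4)` (falling back to 3) marker spheres onto candidates
are scored by mean absolute distance mismatch.  Enumeration is exhaustive up
to 10 candidates (at most P(10,4) = 5040 assignments — cheaper and simpler
than a combinatorial-optimization fallback); more simultaneous candidates is
treated as clutter and rejected.  The best assignment is accepted only if its
maximum pair mismatch is ≤ 5 mm (≈ 3.5 σ of the pairwise-distance noise at
1 mm center noise) and the best *conflicting* assignment — one that pairs a
shared candidate or sphere differently — is worse by ≥ 1 mm mean mismatch.
Two mutually consistent partial assignments are not ambiguous; this
distinction is what lets a frame with one gated-out distance still yield a
correct 3-sphere pose instead of a false ambiguity error.  Both failure modes
raise typed exceptions, and the distance-gap design of the default marker
keeps silent mis-assignment probability negligible (0 in 4000 seeded trials
with 1 mm noise and a spurious detection).

**Kalman filter.**  One 9-state constant-acceleration filter per sphere
(position, velocity, acceleration per axis), measuring position only,
operating on the corrected centers in world coordinates — the registration
consumes centers, so filtering after the correction keeps the filtered
quantity and the registered quantity identical.  Covariances are
`Q = σ_Q·u·I₉` and `R = σ_R·u·I₃` with the conventional small scalars
σ_Q = 1e-4, σ_R = 1e-3 (static) or 1e-4 (dynamic) interpreted on a m² scale
and converted to mm² by `u = 1e6`; this unit convention is the package's
documented choice, and an alternative discretized white-noise-jerk `Q` is
available (`q_model="white_jerk"`).  Initialization: first measurement as
position, zero velocity/acceleration, `P₀ = 10³·I`.  A track resets after
more than 5 consecutive misses, or immediately when the innovation exceeds
25 mm — far above any noise innovation (≈ 3 σ ≈ 10 mm) but far below the
inter-pose jumps of a repositioned marker, so the filter re-initializes at
pose changes instead of dragging a long transient through the statistics.
The update uses the Joseph form and re-symmetrization for covariance health.

## The synthetic camera

`render_frame` produces a 512×512 AB/depth pair.  Default optics: focal
350 px, principal point (255.5, 255.5) — a ~72° field of view.  The rig adds
a small fixed reference-camera→depth-camera extrinsic so the two-transform
world chain is genuinely exercised.

**AB rendering** draws each sphere as a Gaussian intensity profile (the IR
bloom of a retroreflector) of width σ = clip(0.35·R_sil, 1, 5) px, centered on
the *exact projection of the sphere center*, with compact support at 7 σ.  No
IR radiometry is modelled — the tracker needs detectable, localizable blobs,
nothing more.  Two properties follow: (i) a Gaussian of σ ≥ 1 px sampled on
the pixel grid has a centroid equal to its true center up to aliasing terms
below 1e-7 px, and (ii) the blob center coincides with the quantity the
tracker must estimate.  The silhouette centroid of a real sphere image is
offset from the center projection by O((r_s/z)²·f) px (≈ 0.02 px here); that
offset is treated as part of the bloom model, not reproduced.

**Depth rendering** fills each sphere's silhouette (exact per-pixel
ray–sphere discriminant test, dilated by 2 px so bilinear sampling at the
blob center always has valid neighbours) with the *flat* range
`‖camera→center‖ − r_s` — the exact nearest-surface range on the central ray,
which is the only depth the tracker samples.  Together with the exact ray
evaluation this makes the zero-noise pipeline algebraically invertible
(measured: < 6e-8 mm, < 4e-8° over a full 20-pose run), which in turn makes
the end-to-end exactness test a sharp regression guard.  A
`shading="curved"` option renders the physical per-pixel nearest-intersection
range instead, for studying the curvature-induced bias of off-center sampling.

**Noise model** (`NoiseModel`, defaults are the study conditions):

| parameter | default | meaning |
|---|---|---|
| `depth_sigma` | 2.0 mm | sphere-level random depth error per frame (matches the 1.5–2.5 mm published for this camera class over 0.3–1 m) |
| `depth_common_fraction` | 0.85 | fraction of that *variance* shared by all spheres in a frame (global time-of-flight error) |
| `depth_bias_sigma` | 1.0 mm | per-(pose, sphere) systematic offset, constant in time — emulates lookup-table miscalibration |
| `depth_pixel_sigma` | 0.5 mm | per-pixel depth noise inside each disk |
| `ab_background` / `ab_sphere` / `ab_sigma` | 800 / 58000 / 150 | AB levels and noise (16-bit scale) |
| `pixel_sigma` | 0 px | blob-center jitter (angular measurement error) |
| `dropout_prob` | 0 | per-sphere per-frame detection loss |

The common-mode/bias decomposition is the deliberate, scientifically motivated
part: a sphere-level error that shifts all spheres together moves the
estimated *translation* but cancels in *rotation*, while a systematic
per-viewpoint bias is untouchable by temporal filtering.  This is exactly the
structure needed to reproduce the characteristic finding that a Kalman filter
improves translation accuracy but leaves rotation accuracy essentially
unchanged; with the defaults the seeded study run shows translation RMS
falling ~25 % under filtering while rotation RMS changes by well under 20 %
(the rotation change fluctuates around −15 % across seeds, since a 20-pose
run draws only 80 bias values).  For retroreflective targets the physical
rationale is that per-pixel shot noise is small at such high SNR, leaving
global timing/temperature effects and calibration residuals dominant.

**Experiment generators.**  The static protocol samples 20 poses stratified
over 0.3–1.0 m (shuffled order), free yaw, tilt limited to ±15°, 30 frames
per pose at 45 Hz, with per-pose systematic biases.  Pose sampling rejects
configurations whose projected blobs would come closer than the detector's
centroid window plus blob support (≈ 14 σ + 8 px) — the simulated counterpart
of the line-of-sight constraint under which such markers are used; merged
blobs are untrackable for any implementation, though the renderer itself
handles overlap fine (nearest surface wins per pixel).  The dynamic protocol
is a C²-smooth trajectory: a pure x-sinusoid lead segment (40 mm, 0.5 Hz, 4 s)
for temporal calibration, after which multi-axis translation and limited x/y
rotation sinusoids ramp in through a quintic smoothstep; an optional clock
offset shifts the ground-truth ("reference tracker") timestamps.  All
generators draw sphere-level randomness eagerly from the seed and image-level
noise from per-frame child seeds, making bundles bit-reproducible and cheap
(frames re-render lazily on iteration).

## Calibration and alignment

**US spatial calibration** converts stylus-tip pixels to mm using the known
pixel spacing (default 512×512 px at 0.078125 mm/px, a 40 mm linear-probe
field), landmark-registers them onto the simultaneous tracker-frame tip
positions (≥ 3, non-collinear; 8 by default), and closes the loop with the
recorded static marker pose: `marker_from_image = (OT_T_M)⁻¹ · OT_T_US`.
Whether spacing should be solved rather than taken as known was an open
choice; it is taken as known (US stations report it), and a residual scale
check (mean |tracker-span − image-span| per pixel) is reported so a wrong
spacing is visible.  The loop-closure identity holds to 1e-9 by construction
and is asserted.  On clean synthetic scenes recovery is exact (≤ 1e-6 mm/°);
under 0.5 mm tip noise the median translation recovery error over 100 scenes
is ≈ 0.65 mm.

**Pivot calibration** solves `R_i p_tool + t_i = p_world` by linear least
squares; rotation diversity is checked via the condition number of the
stacked system (> 1e8 → error; pure translations are the canonical failure).

**Temporal alignment** projects each trajectory onto its own principal motion
axis (frame-invariant up to sign; the sign is fixed by orienting the axis's
dominant coordinate positive), resamples both signals to the lower of the two
rates, mean-centers, and takes the parabolic-refined argmax of the signed
cross-correlation.  An earlier design maximized |correlation| to dodge the
sign ambiguity, but that aliases pure sinusoids by half a period; the
deterministic sign convention resolves the ambiguity whenever the two frames
are not mirrored, which covers the intended use (and the simulation).
Injected lags of ±{1, 10, 37} samples at 45 Hz are recovered within
0.22 samples.

## Evaluation

Accuracy uses relative motions only, so no registration between the tracker
and the reference is needed and the metrics are invariant to either system's
base frame (property-tested).  The static harness pairs sample *s* of each
pose with sample *s* of the reference pose; `d_e,RMS` is the RMS of the
sphere-distance error over the samples of one pose, and its distribution over
(pose, sphere) is what the summary tables and the error-vs-distance report
describe.  Per-axis translation/rotation rows summarize per-pose RMS values;
magnitude rows summarize per-sample magnitudes.  Quantiles are linear
interpolation between order statistics.  The dynamic harness first estimates
the clock offset from the lead segment, matches each tracked frame to the
nearest ground-truth timestamp after lag removal (the trajectories here share
one frame rate, so nearest-neighbour matching is equivalent to downsampling),
and scores against the first tracked pose.

A property worth knowing when reading the pose-level numbers: the relative
pose error's translation component contains a term `δθ × t_rel` — the
reference-pose rotation error acting over the relative translation between
poses.  With per-pose rotation errors of 1.5–2° (driven by the systematic
bias) and inter-pose separations up to ~0.7 m, this coupling dominates the
static `‖t_e‖` statistics (~10 mm medians under the default noise), which is
why the sphere-level `d_e,RMS` (~1.4 mm median filtered) is the better-behaved
position-accuracy readout and the one mirrored in the worked example.

## Problem sizes

The shipped study runs are sized for quick, repeatable execution: the static
protocol at its full 20 × 30 frames, the dynamic run at 16 s × 45 Hz, the
zero-noise inversion at 20 poses × 3 samples, calibration statistics over 100
scenes, and correspondence robustness over 1000 trials.  A full
`scripts/acceptance.py` run takes about a minute on one CPU.

## Limitations

* The simulator's world pose is exact: headset self-localization drift (which
  can reach centimetres room-scale) is explicitly not modelled, so all results
  characterize the marker-tracking pipeline, not a moving-headset system.
* No photorealistic IR: blob appearance is a Gaussian bloom; specular clutter,
  partial occlusion by hands/arms, and merged blobs at grazing configurations
  are not part of the generated protocols (the detector's circularity and
  area gates, and the correspondence errors, are the defenses the pipeline
  offers).
* The default marker geometry is a constructed stand-in with deliberately
  well-separated unique distances; real tool geometries may be less favorable
  for distance-based correspondence.
* The lookup table is an ideal pinhole; real tables are calibrated and
  imperfect.  The systematic per-viewpoint depth bias in the noise model is a
  proxy for that imperfection, and `LookupTable.entries` can be perturbed
  directly for targeted studies.
* Wall-clock tracking rate and display latency are hardware properties and
  out of scope.
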