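# Methods

This note records the models, conventions, numerical choices and known
limitations behind `clcfm3`. Everything empirical stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Coordinate and camera conventions

Right-handed world frame in millimetres; the turntable axis is +Z and the
disc plane is Z = 0. A camera pose is the world→camera map
`x_c = R x_w + t` with the camera looking down its own +Z; the centre is
`−Rᵀt`. Pixels are 0-based, origin top-left, x right, y down, centres at
integer coordinates. Rotating the object by +θ is represented as a camera at
azimuth −θ about the axis; each view's `azimuth_deg` records the stage
rotation `rotation_index × step_deg`, and all angular logic (grouping, mask
fans) uses circular differences of these azimuths, which are sign-invariant.

"Depth" always means distance along the viewing ray (the quantity a stereo
matcher perturbs at a mismatched boundary), never the camera-frame z. The
intrinsics are a single shared pinhole with a 2-coefficient radial
distortion `x' = x(1 + k1 r² + k2 r⁴)`; synthetic data is rendered
distortion-free. Richer distortion models (thin prism, tangential) are out
of scope.

## CLCFM alignment

**Grouping.** Rotation stop `r` joins group `(r mod G) + 1`, all camera rows
together. Group 1 therefore spans the whole circle at spacing
`G × step_deg` and the ring's wrap-around is inside the very first bundle
adjustment — this is what "closed loop" buys: no drift accumulation around
an open chain. The processing order interleaves the two halves
(`1, 1+⌈G/2⌉, 2, …`), so after every stage the processed azimuths are as
evenly spread as they can be; the suite checks that the largest azimuth gap
never grows across stages. `G` defaults to 6; for other ring sizes it is a
config parameter.

**Per-stage alignment.** Stage 1 bootstraps from an essential-matrix pair
(8-point algorithm on normalized coordinates, cheirality vote over the four
decompositions), chosen among the top-matched candidate pairs as the one
whose median triangulation angle is closest to 15°, ties broken by lowest
view id. Remaining views register by DLT PnP (≥ 6 correspondences, sign
fixed by cheirality) followed by a per-view Levenberg–Marquardt pose refine.
Later stages PnP the new views against the existing tracks — the previous
stage's poses, points and intrinsics are the warm start, verified by a test
that snapshots them on stage entry. A one-view first group (the
`G = n_rotations` degenerate schedule) is held pending until a second view
arrives.

**Bundle adjustment.** Global over all registered poses, all triangulated
tracks and the shared intrinsics. Residuals are pixel reprojection errors
under a Huber loss (delta 2 px); behind-camera projections get a large
constant residual with zero gradient. The solver is a Schur-complement
Levenberg–Marquardt written for this package: analytic sparse Jacobian
(including the closed-form derivative of the rotation-vector map), IRLS
Huber weights, elimination of the 3×3 block-diagonal point block, and
multiplicative damping with accept/reject steps. Termination: two
consecutive accepted steps with relative cost decrease below 1e-12, a
rejected step after 8 damping increases, or 100 iterations. Gauge freedom
is removed by excluding the first registered view's pose from the parameter
vector and pinning the bootstrap-pair camera distance with one soft
residual. scipy's trust-region least squares was measured to creep for
thousands of LSMR iterations on this problem class without reaching its
tolerances; the dedicated solver converges in tens of iterations.

**Self-calibration and its limits.** On a two-row rig (24×15°, rows at 150
and 450 mm, 700 mm radius, 0.5 px noise) the BA recovers a 6%-off initial
focal to within 0.5% and camera centres to under 1 mm RMSE — the acceptance
suite runs exactly this. On a *single-row* ring the self-calibration
problem is degenerate: all camera centres are coplanar with constant tilt,
and the cost surface has a flat focal ↔ k1 ↔ depth valley along which focal
drifts by several percent with no reprojection penalty. The pipeline
therefore fixes the calibrated intrinsics whenever `camera_rows == 1`
(`AlignConfig.optimize_focal/principal_point/distortion = False`), the
standard photogrammetric practice for such rings; multi-row rigs
self-calibrate. This is why the physical studio uses several cameras at
different heights.

**Metric integration.** SfM output is defined up to a similarity. Before
densification the coded targets are triangulated in the reconstruction
frame from their (noisy) image positions and fitted to the known layout
with a closed-form similarity (Umeyama), which carries the poses into
millimetres — the targets' stated role as reference points for integration
and scale.

## MMM densification

**Pair baseClouds.** One stereo job per (row, rotation) pair of adjacent
stops, wrap-around included: a rig of `R` rows and `n` stops yields `R × n`
jobs. The depth backend is a contract: the oracle renderer (tests,
simulation studies) or classical rectified block matching — Fusiello-style
rectifying rotation with the x-axis along the baseline, ZNCC over a 7 px
window, winner-take-all with parabolic sub-pixel refinement, left-right
consistency ≤ 1 disparity, minimum score 0.3. On a 320×240 random-dot slab
the block matcher's median ray-depth error is below 1% of depth. Valid
depths are backprojected along the reference view's rays, colored from the
reference image, and tagged with the pair id (tags survive carving and
merging).

**Mask fans and carving.** The fan of a pair is every view (all rows) whose
azimuth is within `fan_deg / 2` of the pair's mean azimuth; at 72×5°×4 rows
and the default 90° fan that is exactly 72 mask images, the pair's own
views included. Carving is existential: a point is deleted iff at least
`min_bg_views` (default 1) fan views see it project — in front, in bounds,
nearest-pixel lookup — onto background. Out-of-bounds and behind-camera
projections abstain: a view that cannot see a point carries no evidence
against it. Consequences held by the suite: points whose projections land
on foreground in every fan view are never removed; removal sets are nested
over fans 50° → 90° → 180° → 360°; at a 360° fan the surviving cloud is
exactly hull-consistent, and 100% of injected out-of-hull flying pixels are
deleted. Internal noise (points inside the plant volume) is invisible to
silhouette carving by construction and is left untreated.

**Resolution caveat.** At the test resolution (320×240) a 2.5 mm stem at
700 mm subtends 1–2 px, so nearest-pixel mask lookups alias: true surface
points on thin stems are frequently carved because some view's pixel-centre
ray misses the stem. This is the small-scale image of the real trade-off
(wider fans delete true stem/leaf points) and is why `dilate_radius` exists
as a mask-protection option (default 0). At production resolutions
(6000×4000) the effect shrinks by the resolution ratio.

## Synthetic scenes

The generator emulates a plant imaging studio: an acrylic disc (radius
175 mm) on a rotation stage, three 25×15×1000 mm pillars just outside the
disc wearing deterministic random-dot texture, coded targets at the disc
centre, at eight 45° positions 150 mm from the centre, and every 200 mm up
each pillar; one or more camera rows on a 700–1500 mm radius with a fixed
angular step. The plant is 3 capsule stems (radius 2.5 mm, height
~350 mm) and 6 elliptical leaves (~45×28 mm semi-axes) attached at random
heights and azimuths — enough clutter that leaf silhouettes overlap from
some viewpoints, which the suite verifies. Rendering is an analytic CPU ray
caster (sphere, capsule, ellipse, oriented box): masks are exact
silhouettes, depth is exact ray distance, and texture is a hash of the
quantized 3D hit position, so surface dots are view-consistent for feature
matching. Default image size 320×240 (focal 320 px ≈ 53° field of view),
configurable upward.

What the generator does **not** emulate: photometric effects (shadows,
specularity, blur, noise), leaf curvature and serration, wind motion,
background clutter, and real stereo-matcher failure statistics — injected
flying pixels follow the idealized geometry (boundary ray, ±20–25 mm depth
perturbation). Passing tests therefore certify the scheduling, estimation
and carving machinery, not detector robustness on photographs.

**Feature front-ends.** The oracle front-end projects ~260 known scene
points (half plant surface, the rest structure + targets) with i.i.d.
Gaussian pixel noise, treating the scene as transparent; it isolates the
alignment machinery from detector quality. The image front-end (Harris
corners, ZNCC patch descriptors, ratio + mutual checks, union-find track
linking) exists for image-based runs and is smoke-tested, but no claim of
parity with production matchers is made.

## Cloud operations and evaluation

Voxel subsampling keeps one centroid per occupied 0.5 mm cell, grid
anchored at the origin (documented so counts reproduce); centroids stay in
their cells, making the operation idempotent. Cloud differencing bins
nearest-neighbour distances into half-open intervals
[0,1), [1,2), [2,3), [3,22) mm plus overflow, and reports the below/above
3 mm split with *below* meaning `d < 3` — the boundary convention is this
package's documented choice. PLY output is binary little endian
(x, y, z float32 mm; colors uchar); ASCII is read back as well.

Scale fitting is the closed form `s = Σ d_obs·d_known / Σ d_obs²` over
target pairs with known separations; it is exact on noise-free data for any
true scale. The repeated study (`metric_accuracy_study`) reruns the whole
pipeline per seed and reports per-pair mean, SD, difference of means, and
the stricter per-measurement mean |error| across all (pair, run)
combinations. Study conditions: 24×15°×1 row, 320×240, 700 mm radius,
0.5 px noise, 10 seeds drawn via `SeedSequence.spawn` from the master seed;
scale from the 300 mm ring-diameter pair, 19 remaining pairs measured
(centre–ring 150 mm, ring-adjacent ≈114.8 mm, pillar 200 mm). Problem
sizes throughout (24 stops, 320×240, ~260 tracks) are chosen as the
smallest at which every effect of interest is visible.

## Known limitations

- No image-based decoding of coded-target bit patterns; target image
  positions come from known geometry (synthetic setting) rather than marker
  detection.
- Carving cannot remove internal noise, by design.
- The block matcher assumes zero distortion and modest perspective
  difference between adjacent stops; it is a reference backend, not a
  production MVS.
- baseClouds are strictly two-view; a 4-image variant is not implemented
  because its motivation (matcher-dependent hole statistics) is outside
  what the oracle backend can express.
- Masks, depth and texture share one renderer, so mask/depth consistency is
  exact by construction; real segmentation error is modelled only through
  the nearest-mean classifier path.
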