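# Methods

## The synthetic body

The animal is an implicit surface: a superellipsoid torso (half-length
a, half-width b, half-height c; cross-section exponent 0.85 gives the
slightly squared barrel of a dairy cow), four capsule legs slanted
fore/aft like a standing animal, a neck/head capsule whose pitch is a
posture variable, a withers bump, and a thin tail capsule, joined by a
polynomial smooth-minimum (blend radius 6 cm) and triangulated with
marching cubes. Marching cubes guarantees a watertight, consistently
oriented mesh; a sub-voxel lattice shift is retried automatically in
the rare degenerate configurations where the isosurface grazes grid
nodes. The mesh is translated so its lowest vertex sits exactly on the
ground plane z = 0; x is the longitudinal axis with the head toward
+x.

`mesh_resolution` sets the sampling pitch (50 mm at level 1, halving
every two levels; the default level 4 gives ≈ 18 mm and ≈ 60 k faces).
Ground truth (`true_traits`) is evaluated on a mesh two levels finer;
for the pure-ellipsoid degenerate preset, volume, chest depth and the
girths use closed forms (the girths via the complete elliptic
integral).

The adult preset was calibrated once so that its trait vector matches
published adult-cohort means (total volume 764 L, surface 7.20 m²,
withers height 1.454 m, hip width 0.575 m, buttocks width 0.537 m,
chest depth 0.811 m, abdominal girth 2.632 m) within 10 % on every
trait. A smooth implicit body carries less skin area per litre than a
real cow (no ears, folds, udder detail), which is why surface sits
~8 % below and volume ~4 % above the cohort means — the closest joint
fit this family admits. The heifer preset is the adult preset scaled
anisotropically (heights, widths and length separately) to the
heifer-cohort means. Herds draw per-animal axis scales from
N(1, 0.035).

Landmarks are found by bisecting the implicit function along probe
rays: the withers at the top of the shoulder region, hip/pin landmarks
at the lateral extremes of their transverse sections (stations at 16.5 %
and 13.5 % of body length from the tail), shoulder and buttock tips by
oblique horizontal probes. All landmarks therefore lie on the surface
by construction.

## Noise model and study designs

Three independent layers reproduce the structure of a validation
campaign:

* **click jitter** (default SD 4 mm, isotropic) perturbs landmark
  coordinates and station positions on every repeated identification —
  the only noise source under repeatability conditions;
* **posture** (head pitch SD 0.06 rad; stance SD 12 mm) is re-drawn
  per acquisition session and re-meshes the body. Head pitch couples
  into standing height through a lever term (0.25 m per radian,
  ≈ ±2 cm for typical pitches), emulating the posture sensitivity of
  withers-height measurements;
* **surface noise** (SD 2 mm along vertex normals) is per-session
  reconstruction roughness.

A repeatability design is n_subjects × 1 session × n_repeats; a
reproducibility design adds sessions. Within a (subject, session) pair
the mesh object is shared and only the clicked landmarks differ. Seeds
split deterministically per (subject, session, repeat), so studies are
bit-reproducible.

In measurement tables, TV and TS are derived from PV and PS through
the published conversion equations — the partial-image workflow of
interactive measurement — so the "complete volume" trait inherits
click variability as it does in practice. With the default calibration
all trait CVs fall below the 4 % quality threshold, linear-trait
repeatability CVs sit in the expected sub-2 % range, and girth CVs are
markedly smaller than field values: on a smooth synthetic body a small
station shift barely changes a circumference, whereas real torsos are
bumpy. Passing these panels therefore demonstrates correctness of the
estimators and the noise plumbing, not a quantitative prediction of
field CVs.

## The capture simulation

Cameras are pinholes (z forward, x right, y down). Depth maps hold
principal-axis (z) depth, the convention of RGB-D hardware, rendered
by a numba-jitted z-buffer rasteriser with perspective-correct 1/z
interpolation — exact for planar triangles, so a frontal plane at
distance d renders as d everywhere to machine precision. Stereo
matching is not simulated; additive Gaussian noise and depth
quantisation (default step 2 mm) stand in for stereo error.

Bilateral smoothing (spatial radius 3 px, range sigma defaulting to
3× the quantisation step) removes the staircase artifact — ≥ 3×
residual-RMS reduction on quantised planes — while depth
discontinuities much larger than the range sigma move by less than a
millimetre. Back-projection lifts valid pixels to world points with
normals from local depth gradients, oriented toward the camera.
Pairwise extrinsic calibration from checkerboard corners solves the
orthogonal Procrustes problem by SVD (Kabsch), with a singular-value
collinearity guard; merging concatenates posed clouds with optional
5 mm voxel thinning.

### Surface reconstruction

The fused oriented cloud is turned into a watertight mesh by an
implicit moving-least-squares signed distance on a regular grid
(default voxel 12 mm): near the cloud, the Gaussian-weighted mean of
dot(g − pᵢ, nᵢ) over the 10 nearest points (kernel width 1.5 voxels);
far from it, a constant ±4 voxels whose sign comes from one of two
classifiers:

* **flood fill** (no camera information): the complement of the
  morphologically sealed occupancy band is flooded from the grid
  boundary; what the flood cannot reach is interior. Used for plain
  clouds, e.g. the densely sampled sphere, where it reconstructs the
  analytic volume to 0.02 %.
* **space carving** (when the source depth maps are available): a node
  is outside only if some camera observed empty space through it — a
  pixel hit strictly in front of the measured depth, or a no-return
  pixel within range. Never-observed pockets connected to the surface
  band (the belly strip shadowed by the legs, the body interior)
  count as body; other unknown regions (camera shadows on the floor,
  out-of-view corners) are empty. This mirrors how screened-Poisson
  pipelines close unscanned holes, and is robust to the ~1 % of
  surface a physical rig cannot see.

The animal is assumed to stand on an opaque floor: the flood/carve
cannot pass below the ground plane and the bottom ≈ 2 voxels are
forced outside, closing the unscannable undersides of the feet with
flat caps (the wedge of air under a curved foot around its contact
point is never visible to any camera and would otherwise connect the
body interior to the outside). Marching cubes on the combined field,
followed by selection of the largest watertight component, yields the
fused mesh. A scan that does not enclose a volume (a hemisphere, a
partial pass) raises a structured `ReconstructionError` rather than
returning a silently bad mesh.

### The default rig

Fifteen cameras in three transverse arcs (five per arc at ±115°,
±57.5° and 0° from vertical; arcs at x = ±1.05 m and 0) at 1.8 m from
the animal axis, 848×480 pixels with a 75° horizontal field of view.
Low cameras aim below the belly so their view sweeps the floor next to
the animal — without this, the floor strip in the body's shadow is
never observed and space carving cannot classify it. End arcs aim
inboard to keep head and tail in frame. These poses are declared
design, not a reproduction of any hardware layout; the rig is fully
configurable and serialisable to YAML. With this rig, ≥ 99 % of the
default body surface is sampled within 1 cm and the end-to-end chain
(render → quantise 2 mm → smooth → merge → reconstruct) recovers the
source volume to well within 3 % (typically < 1 %).

## Morphometry numerics

Plane clipping splits crossing triangles exactly, snaps vertices
within 10⁻⁹ m of the plane onto it, chains the cut segments into
loops, and caps each loop with a triangle fan around its centroid
oriented along the outward plane normal; kept faces with an edge
exactly in the plane contribute that edge to the cap boundary.
Volume conservation across any single-plane split holds to 10⁻⁶
relative. PS excludes the flat closure caps (they are bookkeeping for
PV, not scanned skin). Cross-sections delegate to the mesh-plane
intersector and flag the contour carrying the dorsal-most point as
the torso; girth is the convex-hull perimeter of that contour (a taut
tape bridges concavities), with the raw contour length available for
diagnostics.

Traits are invariant to translations that respect the frame
conventions (ground plane, longitudinal axis); volume and area are
invariant to arbitrary rigid motions. Full rigid invariance of the
landmark traits is not meaningful here because WH is defined against
the ground plane and the stations against the longitudinal axis.

## Statistics

σ is the pooled within-animal SD, sqrt(SS_within/(N − k)), identical
to the residual SD of the one-way ANOVA; unbalanced panels are
accepted with df = N − k. CVs always use the mean of the same
measurement population (repeatability and reproducibility panels have
different animals). The 95 % limit uses 1.959964·√2 from the Gaussian
difference-of-two-determinations quantile rather than a rounded 2.8.
Traits are assessed independently; no multiplicity correction is
applied. Device comparison uses ordinary least squares of test on
reference values (r² = squared Pearson correlation) and reports
relative differences against the reference mean.

## Problem sizes

Default test and pipeline sizes are chosen for interactive turnaround:
meshes at resolution 4 (≈ 18 mm pitch), capture at 424×240 with the
full 15-camera rig, reconstruction at 12 mm voxels, Monte-Carlo checks
at 100–200 seeds, and the limit-coverage check at 10⁶ replicate
pairs. All are parameters, not constants.

## Known limitations

* The body family is smooth and symmetric: no udder, ears, coat or
  asymmetric conformation, hence girth/station sensitivity is milder
  than on real animals and simulated CVs under-represent field CVs
  for circumference traits.
* Stereo matching, IR projector physics, sunlight interference and
  motion blur are not modelled; depth error is Gaussian noise plus
  quantisation.
* Landmark placement is simulated clicking on known geometry;
  automatic anatomical landmark detection is out of scope.
* Space carving closes self-occluded patches at the visual hull,
  which slightly over-estimates volume in concave occluded regions
  (immaterial at the default rig's ≥ 99 % coverage).
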