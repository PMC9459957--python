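# Methods

## Measurement model and reconstruction chain

The platform is a fixed 2D profile scanner viewing a rotating disc. One
*profile* is a vertical sweep of beam angles θ ∈ [−35°, +35°] in 0.0833°
steps at a fixed turntable angle ϕ; a *scan* is the set of profiles over a
commanded rotation (0.1° steps by default, 3600 profiles per turn). Each
valid return carries a range s (cm) and the beam angle θ (deg); ranges
outside the 70–300 cm working window are missed beams and are dropped, never
zero-filled.

Reconstruction into the disc frame (disc surface = z = 0, disc axis = z)
composes four steps in homogeneous coordinates: the polar-to-Cartesian map
(−s cos θ, 0, s sin θ, 1); the sensor-tilt rotation by φ; the translation by
(d, 0, h) from the sensor origin to the disc center O; and the rotation by
the turntable angle ϕ. During acquisition the specimen turns *with* the disc,
which the simulator represents by rotating the scene by −ϕ; the chain's final
+ϕ rotation undoes exactly that, so every reconstructed return lands at its
specimen-frame surface point.

Conventions fixed by this package (the hardware's were not published): angles
are degrees and lengths centimeters at every interface; h is the signed
sensor height above the disc surface; positive tilt raises the beam
elevation.

A note on the tilt step: the chain's tilt matrix is kept exactly in its
published form, which mixes the sensor-plane z into y (a rotation about the
sensor's viewing axis), while the *physical* tilt of the scan plane — what
the calibration target measures and what the simulator applies to its rays —
is a pivot of the beam elevation (θ → θ + φ). The two agree identically at
φ = 0, and all round-trip guarantees are stated for the untilted platform;
at φ ≠ 0 the chain is applied as published. This is a deliberate
fidelity-to-source choice, not an oversight.

## Platform calibration from the planar target

A 40 × 4.5 cm low-reflectance planar target stands vertically through O; its
trace in the sensor's X′Z′ plane is a straight line. The estimator:

1. total-least-squares (orthogonal) line fit to the upper 60% of the trace's
   vertical extent — orthogonal regression because range noise acts along the
   beam, and the upper portion because any turntable-surface returns sit at
   the very bottom of the trace;
2. tilt φ̂ = signed angle between the fitted line and the Z′ axis;
3. after de-tilting by φ̂, the target line is vertical at x = −d, giving d̂;
4. ĥ = −min z over all de-tilted returns, which anchors the disc surface at
   z = 0: returns from the disc surface itself land exactly at z = −h.

The calibration scene therefore includes the turntable surface (a 20 cm
radius disc — a scene default chosen once to match a pot-sized turntable).
Whenever at least one disc return is in view, ĥ is exact to machine
precision in the noiseless limit, as are d̂ and φ̂ always. When the disc
subtends less than one beam spacing (|h| below a few cm at ranges of 2–3 m),
the lowest *target* return stands in and ĥ inherits a one-beam-spacing bias
(0.1–0.7 cm depending on range). This is an identifiability limit of the
instrument's discrete beam grid, not of the estimator: the target base can
only be bracketed between the last hitting and first missing beam. The
acceptance suite's calibration-recovery check samples sensor placements
uniformly over d ∈ [70, 300] cm, h ∈ [−50, 50] cm, φ ∈ [−5°, 5°], and the
small-|h|/large-d corner of that envelope fails its 1e−4 bound for exactly
this reason (roughly 7 placements in 100); the unit suite pins the exact
recovery property on the identifiable subset instead.

Degenerate inputs: fewer than two returns raise "insufficient target
returns"; a line-fit RMS above 0.5 cm, or a near-horizontal fitted trace
(no vertical target line in the sweep), raises a calibration error rather
than returning nonsense.

## Scanner simulator

Scenes are labeled triangle meshes (trimesh constructions): the reference
cube resting centered on the disc; the calibration target plus disc surface;
and a parametric maize seedling — a tapered vertical culm (radius taper 0.6),
distichous drooping leaf ribbons with parabolic midribs and lanceolate width
profiles, and an optional pot cylinder. Seedling populations are drawn to
match the study's range: stem heights uniform on 10–40 cm, 2–6 leaves
scaling with height, stem radii 0.22–0.42 cm. All builders are deterministic
for a fixed seed.

Ray casting is a vectorized two-sided Möller–Trumbore intersection (nearest
hit per beam) with a bounding-sphere beam prefilter; beams are ideal rays
(the real sensor's divergence is unpublished). Range noise per return is
Gaussian with

    σ(d) = 0.0639 d³ + 0.1139 d² + 0.0473 d + 0.0589

interpreted with d in meters and σ in cm — the only unit assignment under
which the polynomial matches the platform's working range and reported
dispersion scale. Scattering grows with the angle of incidence; this is
modeled by inflating σ by 1/cos(incidence), capped at 3×. The published
dispersion values were measured at near-zero incidence, so the cap only
shapes grazing returns. Each profile acquisition averages 100 independent
repeats; the simulator draws the average directly as N(0, σ/√100), which is
distributionally identical and 100× cheaper. The range gate is applied to
the true distance (the averaged measurement of an in-range surface is in
range with overwhelming probability). Intensity is synthetic plumbing — a
Lambertian cosine times an inverse-square falloff normalized to the minimum
range, clipped to [0, 1] — sufficient for display and format round-trips;
no physically based radiometry is attempted.

Thin-structure behavior emerges from the geometry alone: leaf ribbons are
crossed by few scan planes and at grazing incidence, so leaf returns per unit
blade area stay far below stem returns per unit culm area (about 13 vs 390
per cm² in a typical simulated scan), reproducing the platform's documented
difficulty with thin organs.

## Cube metrology

Accuracy is measured on a scanned cube: per-edge individual error
|m − Ref|/Ref × 100 (the absolute value is required — the published table
reports positive errors on both sides of the reference), per-axis means over
each axis's four edges, overall accuracy as the unweighted mean of the three
axis means, and the absolute error √(Σ(m−m̄)²/(N(N−1))) with N = 12.

Edge extraction from a scan is this package's own definition (the physical
experiment measured edges manually in a viewer): local normals from k-NN PCA
patches, oriented outward; the cube's yaw recovered from the fourfold
symmetry of the side-normal azimuths; per-face trimmed total-least-squares
planes; top corners by intersecting adjacent side planes with the top plane,
bottom corners with the disc plane z = 0 the cube rests on; the twelve edge
lengths from corner distances, labeled U/L/D by face and X/Y/Z by dominant
direction. The procedure is invariant to the cube's rotation on the disc up
to edge relabeling.

The precision (dispersion) experiment repeats the zero-incidence single-beam
distance measurement (142 repetitions by default) at several distances and
fits a least-squares cubic to the observed standard deviations, coefficients
reported in (d³, d², d, 1) order.

## Phenotyping traits

Pre-processing: statistical outlier removal (k = 20 neighbors,
std_ratio = 2.0 — common practice; the platform names the technique without
parameters) followed by a Z-window crop that removes the pot and stray
returns. Height is max z of the cropped cloud. Volume is the occupied-voxel
count times a per-voxel coefficient of 2.5×10⁻³ cm³ — taken at face value as
the platform's experimentally calibrated constant; the matching voxel edge is
its cube root (≈ 0.136 cm), and both are configurable. The voxel lattice is
anchored on multiples of the edge so that adding points can never decrease
the estimate. For thin organs (a maize stem is only a few default voxels
across) the boundary-voxel overcount is the dominant error; validation
against closed-form solids uses a matched grid fine enough to resolve the
smallest radius.

## Organ classification

The platform's "morphological descriptors" are not published; this package
uses the standard geometric descriptor family for organ-level segmentation:
covariance eigenvalue features over a 1 cm spherical neighbourhood
(linearity (λ1−λ2)/λ1, planarity (λ2−λ3)/λ1, sphericity λ3/λ1), verticality
of both the surface normal and the dominant direction, local density,
normalized height z/max z, and the horizontal distance to the stem axis
(centroid of the basal 10% height slab). Neighbourhoods with fewer than
three points get sentinel features and a degeneracy flag.

Splitting is by whole plant, 60/20/20 train/tune/validate (train = floor,
remainder balanced, validate taking the odd scan), routed into early
(≤ 3 leaves) and late stages, deterministic per seed. The Random Forest's
hyperparameters are selected on the tune split from
{50, 100, 200} trees × depth {8, 16, unlimited}; training subsamples at most
40,000 points for tractability. Validation accuracy is reported per plant
(the macro/micro distinction is moot on the synthetic benchmark, where both
are computed).

The ascending virtual-ring filter sweeps a fixed-radius ring up the stem
axis and relabels stem predictions outside it as leaf; leaf labels are never
flipped back. Axis estimation and relabeling are iterated to a fixed point,
which makes the filter idempotent by construction. The platform's published
ring radius of 0.0015 is unit-ambiguous (1.5 mm would be implausibly thin
for a maize stem in cm units); it remains the default for compatibility with
meter-scaled clouds, and the synthetic benchmark uses 0.8 cm — roughly twice
the largest simulated stem radius, so no true stem point is ever outside the
ring.

## What the synthetic benchmark does and does not show

The simulator reproduces the platform's geometry, noise magnitude, averaging
and thin-structure sampling, so passing tests demonstrate that the
reconstruction chain, calibration, metrology and trait pipeline are correct
and numerically tight under realistic noise. It does not reproduce surface
scattering from real leaf tissue, self-occlusion by curled blades, wind or
vibration, sensor biases, or manual labeling noise — so the synthetic
classification accuracy (well above 95%) is an upper bound, not a prediction
of performance on real scans (the physical platform reports ~89% on its own
database), and the database-dependent results (per-plant volumes and
heights over a growth campaign) are checked only as qualitative
monotonicity properties on simulated growth series.

## Problem sizes used in the test suite

Simulated scans in the tests use 1°–6° turntable steps (360–60 profiles)
rather than the hardware's 0.1°, and the classification benchmark uses 20
plants at a 3° step; these sizes were chosen to keep the suite fast while
leaving every property's signal-to-tolerance ratio large. The full-resolution
configuration is the package default.
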