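# Methods

## Phantom geometry and coordinate conventions

The generic phantom is an 18-year-old, gender-neutral stylized body.
Each body region — upper head (uh), lower head (lh), neck (n), trunk
(tr), arms (ar), legs (lg) — is an axis-aligned cuboid given by its
eight corner points; organs are grids of points inside one region, with
the region assignment stored explicitly in the file (containment-based
inference would be ambiguous for grids near a boundary).

Phantom frame (cm): +x toward the patient's left, +y superior →
inferior (the head is at small y), +z anterior → posterior. The upper
head's superior face sits at y = 1 cm, and the body is symmetric about
x = 0. The chain uh → lh → n → tr → lg is contiguous in y (each
region's inferior boundary equals the next one's superior boundary,
exactly). Arms sit outside the chain: they are two mirrored cuboids
flanking the trunk with the trunk's y-span. The legs are a single
cuboid, and the arm posture is fixed parallel to the sagittal plane;
both are deliberate simplifications of extremity anatomy.

## Scaling and transformation

Sizes S(d, r, a) are tabulated at ages {0.1, 1, 3, 5, 10, 15, 18} y.
F_dis is the ratio to the age-18 size; F_cont interpolates F_dis
linearly within each age interval. Choices at the edges:

* The youngest tabulated age is 0.1 y (1 month), so ages below 0.1 are
  rejected — there is no lower interpolation endpoint.
* Age 18 and above clamp to the age-18 factors (all exactly 1): growth
  is assumed to stop at 18.
* Ages are resolved to the nearest tenth of a year; non-tenth inputs
  are snapped with a warning rather than rejected, to keep the CLI
  forgiving.

The per-point transform is axis-separable (see README for the
equations). Two consequences are used as exact invariants in the tests:
the telescoping y-sum keeps the chain gapless at any age (the shared
boundary values are computed by the identical floating-point expression,
so the gap is exactly zero), and the z-shift gives every region's depth
extent the same mid-plane, at half the scaled reference-head depth.

The "head" length in the z-shift is taken from the upper-head region
alone. Taking uh+lh instead would be defensible; the choice only moves
the common mid-plane, not relative anatomy, and is exposed as the
`head_region` argument of `TransformContext`.

The transform re-bases the phantom at y_t = 0 (the 1 cm generic origin
vanishes) and re-centres depths, so geometric comparisons are made via
extents and relative positions, never absolute coordinates. Heights are
unaffected. All arithmetic is double precision; nothing is rounded
until DICOM serialization.

Arm y-placement under scaling is not uniquely determined by the model
(the arm and trunk y-factors could disagree); arms are re-attached at
the trunk's transformed superior boundary and scale with their own `ar`
factors, and the fixture sets S(y, ar, ·) = S(y, tr, ·) so the question
is moot there. Arm/trunk overlap is tolerated for arms only.

## DICOM frame and export

Reorientation to head-first supine is the rigid map L = 10x, P = 10z,
S = −10y (cm → mm); the superior-most point gets the largest S. The
slice grid is pinned: axial slices at S = S_min + (k + ½)·spacing with
half-open coverage [S_min, S_max), so contour counts are deterministic
(a 100 mm cube at 10 mm spacing yields exactly 10 contours). Default
spacing is 2.5 mm, a typical pediatric CT slice thickness. All ROIs of
one export share a single grid anchored at the phantom's S minimum.

Organ contours are the plane sections of the scipy convex hull of the
organ's points: intersection points of hull edges with the slice plane,
ordered by angle about their centroid (the section of a convex body is
convex, so angular ordering is exact). Tangent sections with zero area
emit no contour. Contours are stored closed with the first vertex not
repeated, wound counter-clockwise in the L–P plane. Coordinates are
written as decimal strings with three decimals, so a write/read round
trip is exact to 0.0005 mm (bound 0.001 mm).

Non-contourable organs (fewer than four non-coplanar points — the
fixture's one-point pituitary) are exported as DICOM POINT ROIs at the
grid centroid with a warning rather than dropped, preserving point-dose
lookup. Fifteen-point kidneys remain contourable under this rule, even
though such coarse grids produce crude volumes.

The synthetic CT series exists because TPSs require an image series to
host structures. The phantom is water-equivalent by construction:
voxels whose centre lies inside any body-region cuboid get 0 HU, all
others −1000 HU. The grid is the phantom bounding box plus a 10 mm
margin; a memory budget (default 512 MB of pixel data) guards against
accidentally tiny voxels. UIDs can be derived deterministically from a
caller-supplied entropy list (the CLI seeds them), making whole files
byte-reproducible; timestamps are fixed constants for the same reason.

## Validation metrics

* Percent difference supports both sign conventions — (F−D)/F (the
  default, with the reference F as ground truth) and (D−F)/F — because
  published dose-metric tables are commonly quoted with the candidate
  sign. Reports round to integer percent for display; full precision
  is kept internally.
* The NMSD between two representations of the same organ pairs points
  by index (both derive from one generic grid, so ordering is shared).
  The mean squared distance has units mm²; the root is taken so the
  statistic is an RMS distance in mm, matching how such values are
  conventionally reported. Unordered point-set distances are out of
  scope.
* Organ mass = reference density × voxelized hull volume. The voxel
  grid is anchored at the hull bounding-box minimum with centres at
  min + (i + ½)·voxel; inside tests use the hull half-space equations
  with a 1e-9 tolerance. For convex bodies the estimate converges to
  the analytic hull volume (a grid-aligned 1 cm cube at 1 mm voxels is
  exact, a right tetrahedron is within 1 %).
* Reference organ masses are sex-averaged and part-summed (e.g. wall +
  contents) before differencing; the difference is phantom − reference.
  Missing reference rows are reported, not fatal.

## Synthetic fixture: what it emulates and what it does not

No public coordinate set or growth-measurement table exists for this
class of phantom, so all quantitative work runs on a seeded synthetic
fixture. Its adult is 176 cm with the head exactly 1/7 of stature; the
growth table's knot statures (55, 75, 95, 109, 138, 167, 176 cm) track
50th-percentile population heights, and the head fraction is 1/4 at
0.1 y falling monotonically to 1/7 at 18 y. Width/depth growth curves
approach adult size early for the head and late for the trunk and
limbs. The age-18 column is pinned to the generic extents so every
factor is exactly 1 there. The seed jitters only organ-grid placement;
regions and the growth table are seed-independent, so different seeds
give structurally identical phantoms.

The fixture is synthetic: organ shapes are rectangular point grids, not
anatomical; the growth table is plausible, not measured. Passing tests
therefore demonstrate the correctness of the scaling, transformation,
export and metric machinery — contiguity, mid-plane alignment, factor
algebra, DICOM fidelity — not the anatomical accuracy of any particular
phantom. Real-data properties that the fixture does not exercise
include irregular organ shapes, sex-specific anatomy and skeletal
detail.

## Problem sizes and numerical tolerances

The test suite and the acceptance script run the full pipeline on the
fixture (20 organs, ~700 organ points) at the ten standard validation
ages, plus 50 uniformly random tenth-ages for the invariant sweeps; the
synthetic CT accuracy check uses 2 mm voxels. Exact-zero assertions are
made only where the arithmetic is identical expression-for-expression
(chain gaps, factor = 1 at age 18, unit-cube voxel count); everything
else uses absolute tolerances of 1e-9 (cm/mm geometry) or relative
1e-9 (volumes), far below any physically meaningful scale.

## Known limitations

Dose calculation itself is out of scope: the package reproduces the
geometry and the comparison arithmetic, not a transport engine. The
phantom has no skeleton, no sex-specific anatomy, and organ volumes
from coarse point grids underestimate true organ size — a known
property of hull-of-grid contouring. RT Plan/Dose objects, DICOM
networking and registration to patient CTs are not implemented.
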