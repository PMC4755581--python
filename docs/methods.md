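# Methods

This note records the models, parameter choices and numerical decisions
behind `vsmc3d`, in the order the pipeline applies them.

## Problem setting and coordinate frame

The input is a registered two-channel confocal z-stack of the arterial
wall imaged in the longitudinal–circumferential plane: channel 1 stains
F-actin (the cell body), channel 2 the nucleus.  Arrays are indexed
`[z, y, x]`; `x` is the vessel's longitudinal direction, `y` the
circumference, `z` radial depth.  Default voxel spacing is
0.412 µm in-plane (a 211 µm field at 512 px) and a 0.25 µm z-step.
The in-plane angle β is measured from +Y toward +X and wrapped into
[−90°, 90°) with exactly ±90° mapping to −90°; the tilt α is the
elevation of a principal axis out of the XY plane, in [0°, 90°].

Assumptions: cells are fusiform (slender, spindle-shaped, convex enough
that their boundary is star-shaped around the nucleus centroid), each
cell contains exactly one nucleus which is co-oriented with the cell,
and the two channels are registered.

## Per-slice preprocessing

* **Coherence-enhancing anisotropic diffusion** (5 iterations,
  dt = 0.15, structure-tensor scale ρ = 3 px, across-edge conductivity
  10⁻³).  The diffusion tensor shares eigenvectors with the smoothed
  structure tensor, so smoothing acts along elongated structures and
  barely across their edges.  Output is clipped to the input range
  (maximum principle).
* **Canny edge detection** with σ = 1.5 px and hysteresis thresholds at
  0.1/0.2 of the whole-stack dynamic range (per-slice normalization
  would amplify noise on nearly-empty slices).
* **Edge cleanup**: the pixel graph uses 8-connectivity with redundant
  diagonal links removed (otherwise thin chains read as braided), short
  dead-end branches (< 5 px) are pruned, remaining junction pixels
  deleted, and every component ordered into a chain with exactly two
  endpoints; cycles are opened.  With a cell center supplied, segments
  are sorted and oriented by clockwise ray angle.
* **Nucleus geometry**: the nucleus mask (fraction-of-maximum threshold,
  0.5) is thinned; the skeleton is pruned to its longest
  endpoint-to-endpoint path (double breadth-first search), the centroid
  is the cell center, and the orientation vector points from the center
  to the long-axis endpoint.  Nearly isotropic masks (axis ratio < 1.2)
  fall back to the image-moment principal axis with a warning.

## Ray-fan edge blocking

Rays are cast from the cell center every 1° of scattering angle θ
(measured clockwise from the orientation vector), each with the
emitting-length bound `l(θ) = lc0(1 + lc1 cos θ)`, `lc0 = 30`,
`lc1 = 5` px.  Read literally the bound is negative near θ = 180°
although the two constants are described as the minimal and maximal
emitting lengths; three reconciliations are implemented:

* `literal` — the raw formula, for fidelity experiments;
* `clamped` (operation default) — clipped into `[lc1, lc0(1+lc1)]`;
* `symmetric` (pipeline default) — `|cos θ|`, so both tails of a cell
  that is symmetric about its center are equally reachable.  The
  clamped form leaves the entire sector opposite the orientation vector
  behind a 5 px horizon, which contradicts the intent of rays
  intersecting the whole cell boundary; the symmetric form restores it.

Extended rays covering the two tail sectors (|θ| within 30° of the
axis) are emitted from the skeleton endpoints whenever a tail-sector
ray runs within 15° of parallel to a local tail edge (and always when
no edges are supplied), because center rays sample a slender tail too
sparsely.  Per ray, segment intersections (computed on the polygonal
chain through pixel centers; equal distances break toward the lower
segment id, making the result order-independent) are ranked by
distance: the nearest is kept, the second recorded, deeper hits treated
as noise.  A segment that is nowhere rank 1 is blocked.  Runs of ≥ 3
consecutive hitless center rays become gaps — Type I when both flanking
retained segments are real edges (class A) of the current cell, Type II
otherwise.

## Edge classification and neighbor attribution

Per segment, class A/B/C follows the intensity evidence: the mean
gradient along the segment must point toward the cell interior and the
second derivative (Gaussian-smoothed Laplacian, sampled 1.5 px to
either side) must be more negative just inside than just outside;
failing either gives class B (another cell's edge).  A passing segment
whose far side (3 px beyond) is also foreground is class C — an edge
shared with a touching cell.  Segments shorter than 3 px are unknown.

In clumps the pipeline adds a geometric attribution that the intensity
tests cannot provide: every detected nucleus defines a finite 3D axis
(3D centroid, principal direction of its voxels, and a plausible cell
half-length of 3.5× the nucleus half-length, capped at 90 px).  Each
edge point is assigned to the cell whose axis is nearest in 3D — the
third dimension matters, because a crossing neighbor shares the (x, y)
track while sitting at a different depth.  Maximal runs of ≥ 5 px that
a neighbor wins (by > 0.5 µm) are cut out of the chain; the cut point
is the discrete analogue of splitting a shared edge at the auxiliary
line between the two cells' axes (the explicit construction is
`split_merged_edge`).  Surviving pieces stay class C so their adjacent
gaps are typed II.

## Gap growing

* **Bilateral spline interpolation** (Type I): for each direction
  across the gap, the support is all of one edge plus the other edge
  from a floating junction index onward; a chord-length Catmull-Rom
  spline (a cardinal spline with tension zero) is fitted through the
  support and the junction minimizing the curvature objective is kept.
  Curvature is measured by turning angles: accumulated curvature is the
  total absolute turning (2π for a closed circle), average curvature is
  that divided by arc length (1/r for a circle) — robust on pixel
  chains.  Two directions × two curvature objectives give four
  candidate fills; the winner has the smallest standard deviation of
  its points' distances to the cell center, ties resolved in fixed
  option order, argmin ties to the smallest index.  Gaps wider than
  4·lc0 are rejected as mis-seeded.
* **Laplace verification PCA** (Type II): along each ray of a group
  (7° wide, within the stated 5–10° band), the intensity profile
  between the nucleus edge and the first far hit is differentiated
  twice; the strongest positive response (the outer falloff shoulder)
  is an edge candidate.  A 5×5 px window walks the candidates: PCA of
  the in-window points gives the local edge direction, a piece is drawn
  from their centroid with length equal to the farthest in-window
  candidate, and the window translates to the piece's end.  Fewer than
  two in-window candidates is a reported failure and the caller falls
  back to interpolation.

Boundary assembly concatenates retained chains and fills in clockwise
ray order (with no gaps the boundary is the retained contour
verbatim), normalizes to clockwise winding (negative shoelace area in
the (x, y) frame), and repairs self-crossings by polygon cleanup,
falling back to a star-shaped reassembly around the center.  The
pipeline additionally applies a 5-point circular moving average to damp
single-pixel detector jitter — off by default in the library function.

## Stable-edge propagation

The overlap of a point with a seed edge is `O = 1 − min d/w`
(w = 5 px, deliberately unclamped below zero so averages stay
informative); stability S averages O over the M = 3 most recent
accepted boundaries.  Per 1° ray bin the maximal-O point is a stable
point when its S is positive; an edge is stable when more than 30 % of
its bins hold one.  Unstable edges are treated as noise and the gap
machinery takes over.  A per-point displacement cap of 3 px per slice
enforces "no abrupt position changes"; clipped loops that fold are
repaired by polygon cleanup.  Up to two consecutive unsegmentable
slices are skipped (a touching neighbor can ruin a single slice); the
3D closing bridges them.

Axial extent is decided by a half-maximum criterion: propagation stops
once the mean intensity in a 3×3 patch at the boundary centroid falls
below half the brightest of the three nearest accepted slices (the
local reference also tracks depth-dependent intensity falloff).  This
cuts the cap where the fluorophore's edge band crosses its half level,
i.e. at the geometric surface.

## Reconstruction and morphometry

Per-slice contours are rasterized and filled, closed with a 3×3×3
structuring element, and components below 4 voxels dropped (a plain
opening would erase legitimate one-slice slabs).  The surface is a
marching-cubes iso-surface at 0.5 on the zero-padded volume, in
physical units, relaxed by 5 iterations of umbrella smoothing at
strength 0.3 (volume shrink stays under 10 %); a curvature-percentile
vertex mask supports selected-region refinement.

* **L** — pixel extent of the XY projection along the moment-fitted
  long axis.
* **W** — mean perpendicular chord over the central 50 % of L
  (averaging several stations, as a manual caliper protocol does).
  The chord per 1 px station is the filled cross-length (pixel count):
  identical to the extent on solid sections but robust to stray rim
  pixels, which matters because the projection is a union over ~40
  noisy per-slice contours.
* **T** — longest per-(x, y)-column z-extent × z-step, over columns in
  the same central portion of the axis: a fusiform cell is thickest at
  its middle, and the restriction keeps a neighbor adhering at a tail
  from masquerading as extra thickness.
* **β** — angle of the projected long axis against +Y; projections with
  axis ratio < 1.05 are flagged indeterminate.
* **α** — arcsine of the |z| component of the first eigenvector of the
  3×3 covariance of surface coordinates.  The size-normalized variant
  (coordinates divided by their SDs first) is kept for comparison; it
  whitens the cloud and is much less accurate, as the phantom sweep
  shows.  Per cell, α is measured on the nucleus voxels by default
  (nuclei are co-oriented and always fully inside the imaged depth),
  with the cell-surface value stored alongside.

Records failing plausibility — fewer than 5 slices, thickness under 3
z-steps, or a projected orientation disagreeing with the cell's own
nucleus axis by more than 8° (a signature of a boundary leaking onto a
neighbor) — are reported as failures, not as numbers, mirroring the
semi-automatic workflow's appeal to the user when tracking fails.

The two-mode orientation distribution is fitted by a two-component
Gaussian mixture (EM, k-means initialization, fixed seed, `reg_covar`
10⁻⁴), components sorted by mean; collapsed fits are flagged
degenerate.

## The virtual phantom

The tilt estimator is validated against ellipsoid phantoms: a UV-sphere
mesh (64 azimuthal × 32 polar samples, poles on the long axis so the
tips are densely sampled — resolution chosen so voxelization error is
far below the 10 % acceptance band) scaled to semi-axes (a, b, c),
rotated out of plane by a predefined tilt, and voxelized by per-column
scanline parity (vertical lines through pixel centers, offset by a tiny
irrational epsilon to dodge edge-degenerate crossings; interior voxels
fill between successive crossing pairs).  Both published sizes — 70 px
and 40 px long axes, with a 7:2 aspect — are swept over tilts of
10–60°.  The bent phantom rotates one end ring about an X axis through
the free pole while the other end is fixed; interior vertices solve the
graph-Laplace equation, so each interior displacement is exactly its
neighbors' mean.  Deformation 0° is the identity.

## The synthetic stack generator

The generator is the package's study condition, not a tuning knob.
Cells are solid triaxial ellipsoids with semi-axes (L/2, W/2, T/2)
drawn from the published statistics (L 62.9±14.9, W 4.6±0.6,
T 6.2±1.8 µm, truncated at physiological floors), β from the two-mode
mixture (−19.4±9.3° / 10.9±4.7°, equal weights), α half-normal with
SD 7.6° redrawn until the tilted body fits the imaged depth (the real
10 µm stacks have the same truncation, which is why tilt statistics
come from nuclei).  Nuclei are co-centered, co-oriented ellipsoids at
0.28/0.5/0.5 of the cell's axes.  Intensity is flat inside each cell
with a raised-cosine falloff across the boundary of half-width 0.4 µm
(a confocal-scale edge width; the half-intensity level sits exactly on
the geometric surface, so an unbiased detector recovers the true
boundary), multiplied by a gentle exponential depth decay
(0.015 µm⁻¹) and combined across cells by maximum; Gaussian read noise
(SD 0.03 of unit amplitude) is added and clipped at zero.

Placement keeps nuclei disjoint and cell bodies non-interpenetrating
(quasi-uniform surface sampling against every neighbor's quadric).
A requested fraction of cells is placed as crossing pairs: the
partner's tail slides over the first cell's tail on the same (x, y)
track, separated in depth by just past the sum of the local
half-thicknesses, with up to 0.8 µm of surface overlap allowed — rigid
ellipsoids standing in for the squeeze of touching cells — so the pair
genuinely occludes and adheres within shared slices.  Truth records
carry exact per-slice contours and the L/W/T values that the
morphometric definitions yield on the continuous solid, so recovered
measurements are directly comparable.

What the generator does not emulate: the microscope point-spread
function (especially axial elongation), photobleaching, refractive
artifacts, intensity texture inside cells, deformed or bent cells, and
nuclei that deviate in orientation from their cell.  Passing tests
therefore demonstrate the algorithmic chain on geometrically faithful
but optically idealized data, not performance on real stacks.

## Problem sizes used

The phantom sweep runs 12 rigid cases (two sizes × six angles) plus
four deformations, in seconds.  Full-pipeline recovery runs one
10-cell stack of 448×448×96 voxels with 25 % crossing pairs and noise
SD 0.03 (a few minutes on one core); the orientation-mixture check uses
5000 sampled angles.  Unit fixtures are a few dozen pixels.

## Known limitations

* Thin cells (T ≲ 4.5 µm) carry a relative thickness bias of up to
  ~10 %: the 0.4 µm edge band and 0.25 µm slice quantization are a
  larger fraction of a smaller chord.
* Cells crossing near their mid-body (inside the central 50 % of L)
  can still contaminate the width of one partner by a few percent; the
  point-level attribution removes most, not all, of the shared-edge
  ambiguity.
* The boundary assembly presumes a star-shaped cross-section around
  the nucleus centroid; strongly bent cells would need multiple seeds.
* Interactive rescue (user-selected key edges) is replaced by override
  files and plausibility gates; cells the gates reject are reported as
  failures rather than repaired.
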