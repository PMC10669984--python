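# Methods

This note documents the geometric model behind `fpdremodel`, the parameters
that matter, the synthetic fixtures the tests run on, and the numerical
choices made where the design was genuinely open.

## Connector detection

**Framing.** The bridge is enclosed in its minimum-volume oriented bounding
box, computed from the convex hull with a deterministic orientation search
(1° granularity, via `trimesh.bounds.oriented_bounds`). An exact minimal box
is not needed: the box's role is to define the anatomical frame and the
mid-planes, not its volume. A box alone cannot name anatomical faces, so the
axes are labeled from orientation hints — approximate occlusal, buccal and
mesial→distal directions, defaulting to world +Z, +Y and +X. The axis with
the largest extent is mesio-distal; of the remaining two, the one most
parallel to the occlusal hint is occluso-gingival; the third is
linguo-buccal. Signs follow the hints. The mid-axis L₁ joins the centers of
the distal and mesial box faces, i.e. the two smallest faces.

**Slicing.** 300 planes (default) perpendicular to L₁, equally spaced over
its length with a half-spacing margin at both ends, so no plane coincides
with a box end face. Each plane/mesh intersection is computed by one
intersection point per crossing mesh *edge* (shared edges of adjacent
triangles therefore produce bit-identical points) and the resulting segments
are chained into closed loops exactly, by edge identity rather than by
coordinate matching. Vertices lying exactly on a plane are nudged to the
positive side by 10⁻¹² mm. On watertight meshes every chain closes; open
chains are dropped with a warning.

**Rectangles and area series.** Per slice, the bounding rectangle of all
intersection curves (sides parallel to the box axes) is clipped by the box
mid-plane E_mid into an occlusal and a gingival sub-rectangle; their areas
form two series over the slice index. This is the literal "divide the
rectangle" reading; the alternative (separate bounding rectangles of the
clipped sub-curves) also dips at necks but is not what we implement.

**Minima.** Both series are smoothed by a centered moving average (default
window 5 slices) and searched for interior local minima with prominence at
least 5% of the series range (`scipy.signal.find_peaks`). A second, absolute
prominence floor of 1% of the series maximum suppresses spurious minima on
near-flat series whose "range" is only discretization ripple (e.g. a
cylinder). Occlusal minima α and gingival minima β are found separately —
connectors may be oblique — and paired by nearest index within 15 slices;
unpaired minima are dropped with a warning. With 300 slices over ~32 mm the
index quantization is ~0.11 mm, well inside the ±0.5 mm recovery tolerance
the tests assert.

**Connector site.** L_o is the occlusal edge of the occlusal rectangle at α,
L_g the gingival edge of the gingival rectangle at β; both run along the
lingual–buccal axis, so they are parallel and (for α ≠ β or different
heights) define a unique connector plane E_midCon. If they are collinear the
slice plane at α is used, with a warning. The local frame has its origin at
E_mid ∩ E_mid2 ∩ E_midCon, x̂ pointing occlusally through E_mid2 ∩ L_o, ŷ
along the buccal axis, ẑ = x̂ × ŷ; E_midCon is the local x–y plane. The
initial area A₀ is the shoelace area of the section loop nearest the origin.

## Connector adjustment

Vertices with |z| < w in the local frame (strict inequality; w = 1 mm
default) are selected. The occlusal law displaces vertices with x > 0 to

    x_new = x − k · d_yz · B(d_xy) · x,   d_yz = |x|,  d_xy = |z|,
    B(t) = (w−t)³·w + 3t(w−t)²·0.9w + 3t²(w−t)·0.1w
         = w⁴ · [Bernstein cubic with control values (1, 0.9, 0.1, 0) at t/w]

so the displacement is quadratic in the distance from the mid-plane (the
x-coordinate) and fades as a cubic Bézier in the distance from the connector
plane, reaching exactly zero at the selection boundary — the deformation is
continuous there. Gingival is the same law on x < 0 (the |x| factor makes it
sign-symmetric: both halves move toward the mid-plane), lingual/buccal swap
the roles of x and y (d_xz = |y| replaces d_yz), and `iso` applies all four
with one shared k. Everything outside the selection, and every coordinate a
law does not govern, is bit-identical to the input.

**Fold-over bound.** Along a line of constant (y, z) the occlusal law is
x ↦ x − k·B·x², which is injective only while its derivative 1 − 2k·B·x
stays positive. Keeping merely the shrink factor 1 − k·B·x positive is *not*
sufficient: two vertices can swap order and invert the surface while all
factors remain positive, which we observed as a non-monotone measured area
near that limit. The exposed bound is therefore

    k_max = 0.99 × min over selected vertices of 1 / (2 · d_yz · B(d_xy)),

minimized over all active sub-laws. Inside this bound the measured section
area is monotone non-increasing in k on every fixture (property-tested at 50
samples).

**Solving k.** The objective k ↦ area(k) is monotone on [0, k_max], so a
deterministic bracketed bisection replaces stochastic optimizers: evaluate
the section area of the displaced mesh at the site's *original* connector
plane (the post-deformation minimum section may migrate; it is not
re-detected), stop when |A₂ − A_input| ≤ 0.001 mm² (default tolerance), cap
at 200 iterations, and fail loudly if the target is below the minimum
achievable area at k_max (reporting that minimum). Targets may be given as
an absolute area or as a reduction fraction; a fraction is resolved to an
absolute area once, against the measured A₀. Only shrinking is supported
(k ≥ 0): enlargement is a different design problem.

## Cross-sections and metrics

Polygon area and centroid use the shoelace formulas; extents are reported in
the site chart (height = occluso-gingival, length = bucco-lingual — the
pairing is an assumption documented here, chosen because the section plane
is perpendicular to the mesio-distal axis, leaving those two in-plane
directions). Second moments of area use the standard polygon moment
integrals about the centroid, diagonalized to principal values; they are
descriptive outputs only, not a stress surrogate. Loops are cleaned of
duplicate/collinear points at 10⁻⁹ mm and normalized counter-clockwise;
self-intersecting polygons are rejected where metrics are requested (the
solver's inner loop skips the validity check for speed — its loops come from
the exact chaining above).

## Mesh I/O, remeshing and Hausdorff QC

STL (binary and ASCII) is parsed and written through `trimesh`; STL carries
no units, so all coordinates are interpreted as mm. On read, duplicate
vertices are merged at 10⁻⁶ mm (raw STL stores three loose vertices per
facet) and degenerate faces dropped; facet normals are recomputed from the
winding on write.

`remesh_uniform` provides approximately uniform triangle densities:
edge-split refinement (`subdivide_to_size`, which leaves the surface
pointwise unchanged) when the target count exceeds the input count, and
grid-clustering decimation otherwise; both calibrate their length scale in a
few passes to land within 20% of the target count (default 120,000
triangles, i.e. a 60,000-quad density with each quad split). Fidelity is
enforced by the same Hausdorff QC used for any mesh pair, not assumed.

`hausdorff_distance` is a symmetric sampled estimate: area-weighted random
surface samples (default 100,000 per side) plus all vertices of each mesh
are measured against the other surface with an exact point-to-triangle
distance (closest-point region classification, candidates from a k-d tree
over triangle centroids, k = 16); max and mean are taken over the pooled
distances. The estimate is deterministic for a fixed seed, which is recorded
in the report. Whether published deviation figures for such pipelines are
one- or two-sided is generally unstated; we chose the symmetric form and say
so rather than guess.

## Synthetic fixtures

`generate_fpd` builds an implicit field — a smooth-minimum union (log-sum-exp,
sharpness 4 mm⁻¹) of n superellipsoid crowns (exponent 4) and n−1
superelliptic neck pieces — and extracts the surface by marching cubes
(default voxel pitch 0.15 mm), guaranteeing a watertight mesh with smoothly
blended, irregular-oval necks. Crowns span 80% of their unit's length (the
end crowns are pushed outward so the tips reach the full length), leaving
gaps that the neck pieces bridge; this makes the neck, not the crown tails,
govern the waist. Each neck's superellipse exponent is solved so its
construction area matches the requested target, and after meshing the neck
dimensions are re-scaled by direct slicing until the measured minimum
section is within 2% of the construction target (≤ 3 rebuilds). Defaults
emulate a 4-unit posterior bridge: 32.5 × 11.7 × 9.0 mm overall, neck areas
33.1 / 28.5 / 33.2 mm² with heights 5.7 / 5.7 / 5.8 mm and lengths
6.8 / 6.0 / 6.8 mm (distal→mesial). Optional white vertex jitter along
normals (seeded) emulates scan noise; jitter 0 is bit-reproducible.

What the fixture does **not** emulate: occlusal morphology (cusps, fissures),
margin lines, gingival embrasure asymmetry, or scan artifacts beyond white
jitter. The generated bridge is bilaterally symmetric about y = 0 and z = 0.
Passing tests therefore demonstrate the algorithm's contracts on clean,
connector-dominated geometry; they do not certify behaviour on pathological
scans (holes, self-intersections) beyond the explicit open-mesh warnings.

`generate_dumbbell` (two spheres plus a sharp-union cylindrical neck; the
neck section is exactly circular) is the minimal detection fixture, and
`generate_cylinder` the null fixture with no connectors.

## Problem sizes used by the test suite

The end-to-end grid (3 connectors × 5 directions × 2 reduction levels) runs
on the default-pitch bridge (≈ 156k faces). Unit and property tests use a
0.3 mm pitch bridge (≈ 39k faces), the dumbbell at 0.2 mm, and analytic
primitives (cube, sphere, torus, cylinder), with Hausdorff sample counts of
500–5,000; these sizes are the package's choice of a fast, representative
regression surface. Detection recovery is swept over 20 seeded generator
specs (3–5 units, varied overall dimensions) at 0.25 mm pitch.

## Known limitations

- Orientation hints must be roughly right; with no hints, a bridge scanned
  in an arbitrary pose will get arbitrary anatomical labels.
- L₁ is a straight line: strongly curved arches (full-arch prostheses) are
  out of scope.
- The adjustment law moves vertices toward the connector mid-planes only; it
  never enlarges, smooths, or checks collisions against antagonist geometry.
- Areas are measured at the original connector plane throughout the search;
  for large reductions the true post-deformation minimum section can sit
  slightly off that plane.
- `iso` uses one shared k for all four directional laws; per-direction k
  values are not supported.
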