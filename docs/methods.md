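# Methods

## Model

A screw entering the quadrilateral surface is modelled as a straight rigid
instrument whose axis runs from some point of the surgical incision to the
entry point on bone. The incision (modified Stoppa: longitudinal, midline)
is reduced to a straight 3D segment carrying `n_viewpoints` uniformly spaced
admissible viewpoints, endpoints always included. Soft tissue, retraction
and instrument bending are not modelled.

The clearance a trajectory must keep from the acetabular articular surface
is the maximal subchondral bone thickness plus the minimal screw radius:
1.2 mm + 1.75 mm = **2.95 mm**. A second clearance of **6.0 mm** (a
configured constant, not 2.95 + 3 = 5.95) adds an error margin of about 3 mm
for intraoperative imprecision. Each clearance is materialised as an offset
("shelled") surface of the articular cap; an entry point is *occluded* from
a viewpoint when the open sight segment crosses that shell — equivalently,
the trajectory would pass closer to the joint than the clearance.

Zone semantics over the admissible viewpoint set V:

| zone | predicate |
|---|---|
| absolutely dangerous (region A) | occluded by the 2.95 mm shell for **all** v in V |
| absolutely safe (outside region B) | clear of the 6 mm shell for **some** v in V |
| relatively dangerous | neither |

The all/some reading follows from the clinical reasoning about points E and
F (an entry proximal to E is safe when approached from the distal incision
end, and vice versa for F): danger persists only where *no* direction works.
The alternative union-over-viewpoints reading is exposed as
`quantifier="union"` but is not the default.

Landmarks, per shell: **E** — the occluded brim point farthest from the
obturator canal as seen from the *distal* incision end; **F** — the occluded
brim point nearest the canal from the *proximal* end; **G**, **H** — the
dangerous-zone points farthest from the canal and from the brim. Auxiliary
points: **K** (perpendicular foot of the foramen top on the brim), **M**,
**P** (perpendicular feet of G, H), **N**, **Q** (brim-parallel lines
through G, H intersected with the foramen rim). Reported distances EK, FK,
GM, GN, HP, HQ are straight-segment lengths in cm, as they would be read off
in a CAD tool, not geodesics. "Perpendicular/parallel to the brim" is
evaluated in the least-squares plane of the analyzed region using the local
brim tangent (central difference at the nearest polyline vertex), because
perpendicularity to a 3D space curve is otherwise underdetermined.

## Numerical methods

**Offsetting.** The shell at distance d is the level set {x : dist(x, S) =
d} of the surface's distance field: the surface is sampled by midpoint
subdivision until every edge is below the sampling spacing (max(pitch,
0.4 mm)); the field is evaluated on a voxel grid (default pitch 0.5 mm) via
a k-d tree, exactly in a band around the level and bounded (1-Lipschitz
argument from a stride-4 subgrid) elsewhere; marching cubes extracts the
level set. For watertight inputs the field is signed by per-grid-line
ray-crossing parity, producing the outward shell only; for open caps the
unsigned field yields a closed shell wrapping the cap, which makes occlusion
well-defined at the rim. Sources of error: cloud sampling (≤ s²/8d ≈
0.01 mm), trilinear interpolation of a smooth field (O(pitch²·curvature)) —
the shell is accurate to ~0.02 mm at the defaults, far inside the guaranteed
2×pitch tolerance. A requested offset smaller than the pitch is refused
(warning + error); d = 0 returns the validated input.

**Occlusion.** Exact per-triangle Möller–Trumbore on the open segment
(endpoint guard 1e-6 mm). Three interchangeable paths: chunked numpy
(reference), a numba kernel with early exit, and a numba kernel with a
uniform-grid broadphase (CSR cell→triangle lists, 3D DDA traversal) for
shells above ~4k triangles. Back-face culling is applied only for closed,
outward-wound occluders, where it is exact. Tests assert exact agreement of
all paths with an independent per-triangle loop oracle.

**Landmark extraction.** E/F are evaluated on the brim polyline densified
to min(0.5 mm, entry-spacing/5). G/H start from the dangerous-zone vertex
argmax (ties at 1e-6 mm resolve to the lowest index) and are then refined on
a local grid (step = entry-spacing/8) in the region's tangent plane using
the same occlusion predicate. Because the distance-to-canal and
distance-to-brim objectives vary by less than a micrometre over a millimetre
of zone boundary, the raw argmax is ill-conditioned; the reported point is
therefore the centroid of the near-optimal plateau (objective within
0.05 mm of the maximum), which is stable under sub-0.01 mm perturbations of
the shell. The analytic-truth oracle applies the identical plateau rule to
the closed-form zone, keeping the comparison meaningful.

**Adaptive accuracy.** All extraction spacings are tied to the entry-point
spacing, so the end-to-end landmark error is first-order in the mesh
resolution once the voxel pitch is scaled along with it (the shell's
silhouette sets the error floor). The recovery tests use 1.0 mm mesh /
0.5 mm pitch against 0.5 mm / 0.25 mm and observe the median landmark error
dropping well below half.

**Degenerate inputs.** Coincident incision endpoints, empty meshes,
zero-area faces, collinear plane fits, empty dangerous zones and
brim-parallel lines that miss the foramen all raise typed errors
(`quadzone.errors`); cohort runs skip and report failed subjects rather than
aborting.

## The synthetic phantom

The phantom reduces the hemipelvis to shapes with closed-form occlusion
geometry, in a canonical left-side frame with the plate in z = 0:

* plate: planar slab (~70 × 100 mm, 4 mm thick), watertight by construction;
* pelvic brim: a flat circular arc (R = 150 mm, half-span 26°) whose apex
  direction is rotated 70° from the body axis, so the brim crosses the plate
  obliquely and near-longitudinally, as the linea terminalis does in a
  Stoppa view;
* obturator foramen: an elliptical hole (semi-axes 20 × 8 mm) whose long
  axis leans up toward the acetabulum (tilt −24°), matching the oblique axis
  of the real foramen; the obturator canal is a fixed rim point, the foramen
  "top" the rim's highest point;
* acetabular cup: a spherical cap (r = 24 mm, half-angle 120°) whose centre
  lies 20 mm *behind* the plate plane. Only the cap's apex region and the
  offset shells protrude medially. This is the load-bearing geometric choice:
  a cup fully in front of the plate would cast full-sphere shadows (~7 cm),
  whereas the protruding-bump regime reproduces the few-cm dangerous zones
  reported for real anatomy;
* incision: an 80 mm longitudinal segment 60 mm above and ~80 mm medial to
  the plate, so sight lines strike the plate obliquely and the end-viewpoint
  shadows slide *along* the brim.

Dimensions are plausible adult scale; none is claimed to be a population
value. All are configurable; `generate_cohort` perturbs the scalar anatomy
multiplicatively (seeded, with feasibility retries), and `scale` applies a
global similarity. A cohort draw must also be *measurable*
(`measurement_feasible`, a fast closed-form check): the shells occlude the
brim from both incision ends and the brim-parallel lines through G/H reach
the foramen rim. This is the cohort's inclusion criterion — a study subject
is, by definition, one on which the measurements can be taken; perturbed
anatomies where E or N is undefined are redrawn. Residual failures at run
time are still skipped and reported by `run_cohort`.

Because the cap is spherical and covers every closest-approach direction
relevant to sight lines from above, a segment is occluded by the shell of
offset d exactly when it passes within r + d of the cup centre. The truth
module evaluates this closed form for zones (shadow conics are also
reported), finds E/F by dense 1-D sampling of the brim (~1 µm) and G/H by
nested 2-D grid refinement (~2 µm) with the same plateau rule, and computes
K/M/N/P/Q by circle/ellipse algebra — entirely independent of the mesh,
ray-casting and marching-cubes machinery it validates. A seeded "lumpy cup"
mode (smooth radial perturbation) has no closed form and is instead checked
against the exhaustive per-triangle ray oracle.

What passing phantom tests do **not** show: performance on real segmented
anatomy (aspherical acetabula, rough meshes, curved quadrilateral plates,
segmentation noise), soft-tissue constraints on the aperture, or the
population statistics of any cohort. The cohort machinery demonstrates the
reporting pipeline, not anatomy.

## Problem sizes used in tests and the acceptance script

End-to-end runs use the default phantom at 1.0 mm mesh resolution, 0.5 mm
voxel pitch and 9 incision viewpoints (~5.7k entry points; the analytic
truth is evaluated on the same aperture, so the viewpoint count does not
bias the comparison), with one 2× refinement for the convergence check.
Integration tests use a 2.5 mm / 1.0 mm / 5-viewpoint configuration, and the
acceptance script adds an 8-subject, 5%-variation cohort at that coarse
setting. The offset oracle uses a radius-24 mm icosphere with 1000 sampled
surface points.

## Known limitations

* The offset is tolerance-based (distance field + marching cubes), not an
  exact polyhedral offset; guarantees are 2×pitch, observed ~0.02 mm.
* Occlusion tests only the offset shell: self-occlusion by other bone and
  the feasibility of actually reaching the entry point through the bony
  window are outside the geometric definition.
* G/H are plateau centroids; on near-symmetric zones the plateau can be
  wide, and the centroid then summarises a genuinely flat optimum.
* The straight-segment incision ignores skin/retractor mechanics; viewpoint
  placement is the user's (or phantom's) responsibility.
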