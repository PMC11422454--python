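# Methods

This note records the models, conventions, numerical choices and known
limitations behind `occlusim`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinate frame and units

All geometry lives in a fixed patient frame in millimetres: x transverse
(right negative, left positive), y vertical (down negative, up positive),
z sagittal (back negative, forward positive). Meshes are assumed already
registered to this frame; registration of scans to volumetric imaging is
out of scope. STL carries no units, so millimetres are asserted by
contract.

Rotation parameters follow the clinical naming: roll about the sagittal
z-axis, pitch about the transverse x-axis, yaw about the vertical y-axis.
The three rotations compose intrinsically in the order roll → pitch → yaw,
i.e. `R = Rz(roll) · Rx(pitch) · Ry(yaw)`, about an explicit pivot (the
lower dental midline in the planning workflow). The axis assignment and
order are a convention of this package — the motions are named in clinical
descriptions but their axes and composition order are not standardised —
and are documented rather than configurable.

Mesh hygiene on load: vertices closer than 1e-6 mm are welded (grid
quantisation), faces with repeated indices or area below 1e-12 mm² are
dropped, and watertightness is *reported*, never required (scanned arches
are often open at the base; only the inside/outside sign of the
occlusogram needs a closed lower surface).

## Proximity queries

An AABB tree (median split on the longest centroid axis, default leaf size
8 triangles) accelerates three queries. Results are independent of leaf
size; the test suite pins tree queries to brute-force enumeration over all
triangles.

* **Point-to-surface distance** is exact (face, edge and vertex cases via
  the standard closest-point region walk), with best-first traversal.
* **Triangle–triangle intersection** uses the plane/interval test with a
  strict-crossing semantic: a pair intersects only if each triangle has
  vertices strictly on both sides of the other's plane (tolerance 1e-9,
  scaled by triangle size) and the intersection intervals overlap by more
  than 1e-9 mm. Touching — a vertex or edge exactly on the other surface,
  coplanar overlap — is *contact*, not interference, matching the physics
  of rigid casts. One consequence: exactly aligned surfaces can
  interpenetrate volumetrically while every local triangle contact is
  tangential (two equal boxes offset along one axis). `meshes_intersect`
  therefore runs a fallback on the box-overlapping candidate triangles,
  probing whether any centroid lies strictly inside the other mesh. Full
  containment far away from the other surface is only detected by the
  pose-collision predicate, which adds explicit vertex probes; for dental
  arches this configuration cannot occur.
* **Inside/outside** is a ray-parity test casting along +z with
  deterministic direction perturbation when a ray grazes an edge, vertex or
  near-parallel triangle, falling back to the generalised winding number in
  pathological cases. The winding number is also exposed separately and
  serves as the independent oracle in tests.

Distances between meshes are sampled at mesh vertices (the occlusogram is a
per-vertex field); no claim of exact surface-to-surface minimal distance is
made, and the synthetic fixtures are built so vertex sampling resolves
every designed feature.

## Occlusogram and contacts

The occlusogram is the signed distance from every upper-arch vertex to the
lower surface, negative where the vertex is inside the (watertight) lower
mesh; with a non-watertight lower mesh the sign is computed anyway but
flagged unreliable. The display ceiling (0.5 mm) clamps only presentation,
never stored values.

An occlusal contact is a connected component of the upper-mesh vertex
adjacency graph restricted to vertices with 0 ≤ d ≤ 0.5 mm — "coherent
area" is not defined operationally in clinical software descriptions, and
graph connectivity is the natural discretisation. The threshold is
inclusive at exactly 0.5 mm ("0.5 mm or less"). Interpenetrating vertices
(d < 0) are never contact members; their presence raises the interference
flag. No minimum region size is applied by default (`min_region_vertices`
= 1). Region area is reported as the sum of member vertices' barycentric
areas (one third of each incident face).

Segmentation into anterior / posterior-right / posterior-left uses a
boundary plane through each upper canine cusp tip, perpendicular to the
local arch tangent (estimated from the incisal point toward the
ipsilateral molar cusp, projected to the occlusal plane); a vertex is
anterior iff it lies on the incisal side of both planes, and posterior
vertices split at the mid-sagittal plane. A simpler sagittal-threshold
mode (`method="zplane"`) exists for fixtures. A contact spanning a
boundary is assigned whole, by the label of the member vertex nearest the
region centroid.

## Occlusion setting

The collision predicate for a pose is: any properly crossing triangle pair
between the transformed upper and the lower tree, plus cheap containment
probes. Poses with minimal distance in [0, 1e-3 mm] and no crossing count
as touching.

**Manual moves and snapping.** A requested delta (translation + rotations
about the pivot) is applied fully if collision-free; otherwise it is scaled
back to the largest collision-free fraction. The fraction search first
scans the path at steps bounded by 0.4 mm of maximal vertex displacement —
a plain bisection could tunnel through thin geometry — then bisects the
first-contact bracket to 1e-4 mm of motion. `snap_to_contact` is the pure
translation special case.

**Spring solver.** The unconstrained optimum of the weighted squared
spring lengths is the closed-form rigid least-squares fit (SVD of the
weighted cross-covariance with determinant correction). If that pose is
collision-free the solver returns it unchanged — this anchors the
constrained algorithm to a known optimum. Otherwise the motion from the
current pose to the fit (translation lerp, rotation slerp) is retracted by
the same scan-and-bisect scheme to first contact, followed by greedy local
refinement: the twelve ± axis moves (translation step 0.05 mm, rotation
step 0.1° about the spring centroid) are evaluated, the best
energy-decreasing collision-free candidate is accepted, and the steps are
halved when none is acceptable, stopping at 1e-3 mm / 1e-3° or when the
energy improvement falls below `tol²`. The procedure is deterministic;
with equal-energy candidates the fixed evaluation order breaks ties, which
in practice favours the smallest motion. At least three non-collinear
spring anchors are required (rank check at 1e-9 relative tolerance);
editing springs and re-running the solver is the supported interaction
model — there is no incremental solver state.

The refinement is local: if the constrained optimum requires sliding far
along the contact surface, the solver may stop at a nearby
energy-decreasing pose. For occlusion setting (approach movements of a few
millimetres toward near-feasible targets) this matches the intended
semi-automatic behaviour, where the operator reviews and edits springs.

## Evaluation statistics

* **Maxillary movement**: landmark deltas `T(p) − p` at UI, UMcusp(r),
  UMcusp(l), reported per axis in patient-frame signs.
* **Jaw relationship**: midline deviation `x(UI) − x(LI)`, overbite
  `y(LI) − y(UI)`, overjet `z(UI) − z(LI)`; molar relationships
  upper-minus-lower cusp differences per axis. Signs are chosen so normal
  Class I occlusion yields positive overbite and overjet; the desirable
  window for both is 0–3.5 mm (index of orthodontic treatment need).
* **Tolerance interval**: mean of the *absolute* gold-standard
  inter-observer differences ± 1 SD of those absolute differences, floored
  at 0. Coverage is the fraction of absolute test differences inside the
  band, with 0.68 as the pass mark. For normally distributed differences
  the asymptotic coverage of this band is 0.684 (the signed-difference
  reading gives 0.6827); both are "approximately 68 %", and the absolute
  form is what the interval definition states. The signed-SD alternative
  is exposed via `use_absolute=False`.
* **ICC**: two-way random effects, absolute agreement, single measurement
  — ICC(2,1) from the ANOVA mean squares
  `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)` — the standard reading
  of "absolute agreement" for intra/inter-rater designs. Bands: good for
  0.75–0.90, very good above 0.90. An all-constant table is returned as
  ICC 1 with a degeneracy flag. Inter-rater tables pool time points as
  separate rows (the pooled reading of "across all time points"); the
  intra-rater design compares time points per observer. No
  multiple-testing correction is applied.
* **Bland–Altman**: differences a − b against averages, limits of
  agreement at mean ± 1.96 SD, per-point table exported for plotting.

## Synthetic arch generator

The generator emulates the study inputs — matched upper/lower arch meshes
with a known surgical occlusion — not anatomy. Each arch is a watertight
solid band (about 6.9k triangles at default resolution: 180 arc × 16 band
intervals) following a parabolic arch curve, arc-length parameterised;
default arch width 55 mm, depth 45 mm, band width 8 mm, with at least six
(default seven) teeth per quadrant defining canine and first-molar
positions as arc fractions.

Occlusion is built vertically: the flat upper occlusal surface sits
`cusp_height` (default 1.5 mm) above the flat lower band. Designed contact
patches are paraboloid cusp bumps (radius 1.5 mm) on the lower surface
rising toward matching shallow fossae (radius 1 mm, depth 0.1 mm) on the
upper, with bump height set so the minimal distance at each patch equals
its designed clearance — 0.2 mm by default, well inside the 0.5 mm contact
window — while all non-designed surfaces stay > 1 mm apart, making the
contact counts robust to mesh resolution. The default patch layout is 11
contacts split 5 anterior / 3+3 posterior, the typical yield of a virtual
occlusion with bilaterally symmetric distribution; the posterior patches
sit at the premolar and first-molar positions. An anterior incisor flange
on the upper band dips below the lower incisal edge — strictly forward of
the lower band plus a 1 mm margin — so that the incisal landmarks realise
the target overbite and overjet exactly (defaults +1.08 mm and +2.25 mm, a
conventional Class I surgical set-up); overjet below 1.4 mm leaves no room
for the flange, in which case it is omitted with a warning. A sagittal
`class_offset` translates the lower arch backward (positive, Class II
tendency) or forward (negative, Class III); it appears in the molar
relationship while the incisal targets are held. The generator validates
feasibility (bumps under the upper footprint, no interpenetration at
truth) and raises otherwise; generation is fully deterministic for fixed
parameters.

What the generator does **not** emulate: crown morphology, scan noise,
occlusal curves (Spee/Wilson), open bites, missing or supernumerary teeth.
Tests passing on these fixtures demonstrate the correctness of the
geometric and statistical machinery, not robustness to real scan
artefacts.

`perturb_occlusion` draws a start pose uniformly (translation in a ball,
per-axis rotations) and rejection-samples until collision-free (at most
100 draws). `observer_noise_tables` emulates the repeated-measures design:
30 cases × 2 observers × 2 time points × 3 methods, with per-case true
offsets (SD 2 mm per axis — the between-patient variability of planned
positions, needed for a non-degenerate ICC), i.i.d. observer noise
(default SD 0.15 mm, which reproduces gold-standard tolerance intervals of
a few tenths of a millimetre), and method-level bias vectors. The default
bias pushes both virtual methods +0.3 mm along z, so the conventional
minus virtual Bland–Altman mean difference at the incisal point recovers
−0.3 mm — the anterior-positioning tendency the pipeline is designed to
detect.

## Problem sizes and defaults

The test suite and acceptance script run at the generator defaults (~6.9k
triangles per arch, 30 simulated cases, 10⁵ draws for the normal-coverage
check, 50 random trials for the closed-form spring anchor, 20 random mesh
pairs for the intersection oracle). Brute-force oracles run on meshes of
at most a few hundred triangles, where exhaustive enumeration is exact and
fast.

## Known limitations

* Contact counting is vertex-based; patches smaller than the mesh edge
  length could be missed on coarse meshes (the generator's patch radii are
  sized ~2× the default edge length).
* The spring solver's refinement is a local search; global optimality is
  guaranteed only when the unconstrained optimum is feasible.
* `meshes_intersect` reports surface intersection; deep containment
  without surface proximity is handled only by the pose-collision
  predicate.
* The evaluation pipeline assumes complete measurement tables (no missing
  cells) as produced by the study design and the generator.
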