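# occlusim

Collision-aware virtual surgical occlusion setting and occlusal contact
analysis for orthognathic planning.

## The problem

Orthognathic (jaw) surgery is planned around a *surgical occlusion*: the
relationship between the upper and lower dental arches that the osteotomy
will establish. Traditionally this is set by hand on printed or plaster
casts; virtual workflows instead move digitised dental meshes on screen.
Unlike physical casts, digital models interpenetrate freely, so a virtual
occlusion tool needs three things:

1. **real-time collision awareness** — the upper model must stop where the
   casts would touch;
2. **an occlusogram** — a map of minimal distances between the opposing
   occlusal surfaces, from which occlusal contacts and interferences are
   read; and
3. **quantitative evaluation** — maxillary movement, the inter-jaw
   relationship (midline deviation, overbite, overjet), the contact count
   per dental-arch segment, and method-agreement statistics against a gold
   standard.

`occlusim` implements this engine end-to-end for triangle meshes (STL) in a
fixed patient frame (x: right −/left +, y: down −/up +, z: back −/forward +,
all mm), plus a synthetic dental-arch generator so that the entire pipeline
is testable with analytic ground truth and no patient data.

## The methods at the core

**Proximity engine.** An axis-aligned bounding-box (AABB) tree over each
arch supports exact point-to-surface distances, triangle–triangle
intersection search and a ray-parity inside test. Two triangles *interfere*
only if they properly cross; surfaces that merely touch count as contact,
mirroring the physical impossibility of interpenetration.

**Occlusogram.** Signed distance d(v) from each upper-arch vertex v to the
lower surface (negative inside the lower mesh). An *occlusal contact* is a
coherent area with 0 ≤ d ≤ 0.5 mm — operationally, a connected component of
the upper-mesh vertex graph restricted to contact vertices. Contacts are
counted in three segments: anterior (canine to canine), posterior right and
posterior left. Any d < 0 is an interference.

**Occlusion setting.** Manual translations and roll/pitch/yaw rotations
about a rotation centre at the lower dental midline are clamped to the last
collision-free fraction of the requested move (bisection to first contact).
The semi-automatic *spring* mode places ≥ 3 corresponding landmark pairs
(uᵢ on the upper, lᵢ on the lower model) and solves

    min_T  Σᵢ wᵢ ‖T(uᵢ) − lᵢ‖²   subject to no interpenetration,

by a closed-form weighted rigid least-squares fit (SVD of the weighted
cross-covariance), retraction along the approach path to first contact when
the optimum collides, and energy-decreasing collision-free refinement.

**Evaluation.** Maxillary movement as per-axis landmark deltas T(p) − p at
the upper incisal point and first-molar cusp tips; midline deviation
x(UI) − x(LI), overbite y(LI) − y(UI), overjet z(UI) − z(LI) with the 0–3.5 mm
desirable window; gold-standard tolerance intervals (mean of absolute
inter-observer differences ± 1 SD, ≈ 68 % coverage expected under
normality); ICC(2,1) (two-way random effects, absolute agreement, single
measurement; 0.75–0.90 good, > 0.90 very good) and Bland–Altman limits of
agreement at mean ± 1.96 SD.

## Worked example

```python
import numpy as np
from occlusim import (ArchParams, ContactParams, SpringSet, generate_arch_pair,
                      compute_distance_field, segment_arch, extract_contact_regions,
                      summarize_contacts, jaw_relationship, perturb_occlusion,
                      springs_align, apply_transform, build_tree)

# synthetic arch pair at ground-truth occlusion (11 designed contacts)
upper, lower, landmarks, truth = generate_arch_pair(ArchParams(seed=1))
tree = build_tree(lower)

# occlusogram and contact counts
field = compute_distance_field(upper, lower, tree)
segmentation = segment_arch(upper, landmarks)
report = extract_contact_regions(field, upper, ContactParams(), segmentation)
summary = summarize_contacts(report)
print("contacts:", report.n_contacts, report.counts)
print("interference present:", report.interference_present)

# inter-jaw relationship at the set occlusion
rel = jaw_relationship(landmarks)
print(f"overjet {rel.overjet:+.2f} mm, overbite {rel.overbite:+.2f} mm, "
      f"midline {rel.midline_deviation:+.2f} mm")

# displace the upper arch, then recover the occlusion with three springs
start = perturb_occlusion(upper, lower, max_translation=5.0, max_rotation=10.0,
                          seed=1, pivot=landmarks.lower_midline, lower_tree=tree)
anchors = np.vstack([landmarks["UI"], landmarks["UMcusp_r"], landmarks["UMcusp_l"]])
springs = SpringSet(start.apply(anchors), anchors)
result = springs_align(apply_transform(upper, start), lower, springs, lower_tree=tree)
err = np.abs(result.transform.apply(start.apply(anchors)) - anchors).max()
print(f"spring residual {result.residual_spring_energy:.2e} mm^2, "
      f"landmark recovery error {err:.1e} mm")
```

Output:

```
contacts: 11 {'anterior': 5, 'posterior_right': 3, 'posterior_left': 3}
interference present: False
overjet +2.25 mm, overbite +1.08 mm, midline +0.00 mm
spring residual 4.04e-29 mm^2, landmark recovery error 3.6e-15 mm
```

The generated pair realises its designed occlusion exactly: 11 coherent
contacts split 5/3/3 across the three segments with no interference, the
incisal relationship equals the generator's set-points (+2.25 mm overjet,
+1.08 mm overbite, centred midline), and after a random 5 mm / 10°
displacement the spring solver returns the upper arch to the true occlusion
to machine precision (the unconstrained optimum is collision-free here, so
the solver coincides with the closed-form fit).

The same workflow is scriptable from the shell:

```bash
occlusim simulate --seed 1 --out demo/
occlusim occlusogram --upper demo/upper.stl --lower demo/lower.stl \
         --landmarks demo/landmarks.csv --out demo/occ/
occlusim agreement --table measurements.csv --design inter --out demo/agr/
```

## Layout

- `src/occlusim/mesh_core.py` — STL/landmark I/O, patient frame, rigid transforms
- `src/occlusim/proximity.py` — AABB tree, distances, intersections, inside tests
- `src/occlusim/occlusogram.py` — signed distance field, contacts, segmentation
- `src/occlusim/occlusion_setting.py` — manual moves, snap-to-contact, spring solver
- `src/occlusim/evaluation.py` — movement, jaw relationship, tolerance/ICC/Bland–Altman
- `src/occlusim/synthetic_arch.py` — parametric arch generator with ground truth
- `src/occlusim/cli.py` — `occlusim` command-line interface
- `docs/methods.md` — modelling assumptions, parameters and numerical choices
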