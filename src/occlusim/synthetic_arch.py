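"""Parametric generator of matched upper/lower dental arches with known
ground-truth occlusion.

No deposited scans accompany the method, so every downstream module is
exercised on stylised arches built to analytic ground truth:

* each arch is a watertight solid band following a parabolic arch curve
  (arc-length parameterised), about 6-7k triangles at default resolution;
* the lower occlusal surface carries paraboloid *cusp bumps* at designed
  tooth positions; the upper occlusal surface is flat with matching shallow
  fossae, so each bump forms one coherent contact patch whose minimal
  distance equals the designed clearance (default 0.2 mm, well inside the
  0.5 mm contact threshold) while all other surfaces stay > 1 mm apart;
* an anterior incisor flange on the upper band dips below the lower incisal
  edge so that the upper/lower incisal landmarks realise the target
  overbite and overjet exactly;
* a sagittal ``class_offset`` displaces the whole lower arch backwards
  (positive, Class II tendency) or forwards (negative, Class III), which
  shows up in the molar relationship while the incisal targets are held.

Teeth are stylised, not anatomical: sufficient for distance, contact,
collision and agreement metrics, and honest about not emulating scan noise
or crown morphology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .mesh_core import Arch, DentalMesh, LandmarkSet, RigidTransform, transform_from_euler
from .occlusogram import SEGMENTS
from .proximity import AabbTree, build_tree, meshes_intersect
from .evaluation import JawRelationship, jaw_relationship

__all__ = [
    "ArchParams",
    "ContactPatchSpec",
    "GroundTruth",
    "ArchPair",
    "GenerationError",
    "generate_arch_pair",
    "perturb_occlusion",
    "observer_noise_tables",
]


class GenerationError(RuntimeError):
    """Requested parameters cannot produce a feasible occlusion."""


@dataclass
class ContactPatchSpec:
    segment: str
    count: int
    clearance: float = 0.2  # mm, designed minimal distance of the patch

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment}")
        if self.count < 0 or self.clearance <= 0:
            raise ValueError("invalid patch spec")


def _default_patches() -> list[ContactPatchSpec]:
    # 11 contacts split 5 anterior / 3+3 posterior: the typical virtual
    # occlusion yield with a bilaterally symmetric distribution
    return [
        ContactPatchSpec("anterior", 5),
        ContactPatchSpec("posterior_right", 3),
        ContactPatchSpec("posterior_left", 3),
    ]


@dataclass
class ArchParams:
    """Generator parameters (mm throughout)."""

    arch_width: float = 55.0
    arch_depth: float = 45.0
    n_teeth_per_quadrant: int = 7
    cusp_height: float = 1.5  # occlusal separation between flat surfaces
    target_overjet: float = 2.25
    target_overbite: float = 1.08
    class_offset: float = 0.0  # + Class II (lower back), - Class III
    contact_patches: list[ContactPatchSpec] = field(default_factory=_default_patches)
    seed: int = 0
    band_width: float = 8.0
    n_arc: int = 180  # intervals along the arch
    n_band: int = 16  # intervals across the band
    bump_radius: float = 1.5
    fossa_radius: float = 1.0
    fossa_depth: float = 0.1
    solid_thickness: float = 6.0

    def __post_init__(self) -> None:
        for name in ("arch_width", "arch_depth", "cusp_height", "band_width",
                     "bump_radius", "fossa_radius", "solid_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_teeth_per_quadrant < 6:
            raise ValueError("need at least six teeth per quadrant")
        for p in self.contact_patches:
            if p.clearance >= self.cusp_height:
                raise ValueError("patch clearance must be below the occlusal separation")


@dataclass
class GroundTruth:
    true_occlusion_transform: RigidTransform
    true_contact_count_per_segment: dict[str, int]
    true_relationship: JawRelationship

    @property
    def total_contacts(self) -> int:
        return sum(self.true_contact_count_per_segment.values())


@dataclass
class ArchPair:
    upper: DentalMesh
    lower: DentalMesh
    landmarks: LandmarkSet
    truth: GroundTruth

    def __iter__(self):
        return iter((self.upper, self.lower, self.landmarks, self.truth))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _arc_tables(width: float, depth: float, n_dense: int = 4001):
    """Arc-length parameterisation of z(x) = depth (1 - (2x/width)^2)."""
    x = np.linspace(-width / 2, width / 2, n_dense)
    z = depth * (1.0 - (2.0 * x / width) ** 2)
    seg = np.hypot(np.diff(x), np.diff(z))
    a = np.concatenate([[0.0], np.cumsum(seg)])
    a -= a[n_dense // 2]  # arc coordinate 0 at the anterior apex
    return a, x


def _curve_at(a_query: np.ndarray, width: float, depth: float):
    """Centerline point and outward normal at signed arc coordinates."""
    a_tab, x_tab = _arc_tables(width, depth)
    x = np.interp(a_query, a_tab, x_tab)
    z = depth * (1.0 - (2.0 * x / width) ** 2)
    dzdx = -8.0 * depth * x / width**2
    norm = np.sqrt(1.0 + dzdx**2)
    # outward normal in the xz-plane (forward at the apex, lateral at ends)
    nx = -dzdx / norm
    nz = 1.0 / norm
    return x, z, nx, nz, float(a_tab[-1] - a_tab[0])


def _heightfield_solid(
    xz: np.ndarray, y_surf: np.ndarray, plate_y: float
) -> tuple[np.ndarray, np.ndarray]:
    """Watertight solid between a heightfield surface grid and a flat plate.

    ``xz`` is (ns, nt, 2), ``y_surf`` (ns, nt); the plate closes the solid
    at ``plate_y`` via side walls and a boundary fan.  Winding is made
    globally outward by the caller (volume sign check).
    """
    ns, nt = y_surf.shape
    surf = np.concatenate([xz[..., :1], y_surf[..., None], xz[..., 1:]], axis=2)
    verts = [surf.reshape(-1, 3)]
    sid = np.arange(ns * nt).reshape(ns, nt)

    faces = []
    for i in range(ns - 1):
        for j in range(nt - 1):
            q = (sid[i, j], sid[i + 1, j], sid[i + 1, j + 1], sid[i, j + 1])
            faces.append((q[0], q[1], q[2]))
            faces.append((q[0], q[2], q[3]))

    # closed boundary loop of the grid
    loop = (
        [sid[i, 0] for i in range(ns)]
        + [sid[ns - 1, j] for j in range(1, nt)]
        + [sid[i, nt - 1] for i in range(ns - 2, -1, -1)]
        + [sid[0, j] for j in range(nt - 2, 0, -1)]
    )
    base = ns * nt
    loop_pts = verts[0][loop]
    plate_pts = loop_pts.copy()
    plate_pts[:, 1] = plate_y
    verts.append(plate_pts)
    center = np.array([[plate_pts[:, 0].mean(), plate_y, plate_pts[:, 2].mean()]])
    verts.append(center)
    cid = base + len(loop)

    nb = len(loop)
    for k in range(nb):
        k1 = (k + 1) % nb
        s0, s1 = loop[k], loop[k1]
        p0, p1 = base + k, base + k1
        faces.append((s0, s1, p1))
        faces.append((s0, p1, p0))
        faces.append((cid, p1, p0))

    v = np.concatenate(verts, axis=0)
    f = np.asarray(faces, dtype=np.int64)
    tm = trimesh.Trimesh(vertices=v, faces=f, process=False)
    if tm.volume < 0:
        f = f[:, [0, 2, 1]]
    return v, f


def _patch_positions(params: ArchParams, half_arc: float) -> dict[str, np.ndarray]:
    """Signed arc coordinates of designed contact patches per segment."""
    n = params.n_teeth_per_quadrant
    f_can = 2.5 / n  # canine centre as a fraction of the half arc
    ant_reach = (f_can - 0.9 / n) * half_arc
    post_lo = (f_can + 0.8 / n) * half_arc
    post_hi = (5.5 / n) * half_arc  # first-molar centre carries the last patch
    out: dict[str, np.ndarray] = {}
    for spec in params.contact_patches:
        c = spec.count
        if c == 0:
            out[spec.segment] = np.empty(0)
            continue
        if spec.segment == "anterior":
            pos = np.linspace(-ant_reach, ant_reach, c) if c > 1 else np.array([0.0])
        else:
            pos = np.linspace(post_lo, post_hi, c) if c > 1 else np.array([post_lo])
            if spec.segment == "posterior_right":
                pos = -pos  # patient right = negative x side = negative arc
        out[spec.segment] = pos
    return out


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate_arch_pair(params: ArchParams | None = None) -> ArchPair:
    """Generate a matched upper/lower arch pair at ground-truth occlusion.

    The true occlusion transform is the identity: the meshes are emitted in
    occlusion, with designed contacts at their stated clearances, all other
    surfaces > 1 mm apart and no interpenetration.  The generator is fully
    deterministic for fixed parameters.
    """
    p = params or ArchParams()
    sep = p.cusp_height
    off = p.class_offset
    oj, ob = p.target_overjet, p.target_overbite
    bw = p.band_width

    # ---- lower arch -------------------------------------------------------
    a_tab, _ = _arc_tables(p.arch_width, p.arch_depth)
    half_arc_l = float(a_tab[-1])
    a_l = np.linspace(-half_arc_l, half_arc_l, p.n_arc + 1)
    x_l, z_l, nx_l, nz_l, _ = _curve_at(a_l, p.arch_width, p.arch_depth)
    t = np.linspace(0.0, 1.0, p.n_band + 1)
    lx = x_l[:, None] + (t[None, :] - 0.5) * bw * nx_l[:, None]
    lz = z_l[:, None] + (t[None, :] - 0.5) * bw * nz_l[:, None] - off

    # designed cusp bumps (world coordinates, after the class shift)
    patch_arcs = _patch_positions(p, half_arc_l)
    centres, heights, counts = [], [], {s: 0 for s in SEGMENTS}
    clearance_of: dict[str, float] = {s.segment: s.clearance for s in p.contact_patches}
    for seg, arcs in patch_arcs.items():
        for a0 in arcs:
            cx, cz, _, _, _ = _curve_at(np.array([a0]), p.arch_width, p.arch_depth)
            centres.append((float(cx[0]), float(cz[0]) - off))
            heights.append(sep + p.fossa_depth - clearance_of[seg])
            counts[seg] += 1

    def bumps(xg: np.ndarray, zg: np.ndarray, radius: float, amps) -> np.ndarray:
        out = np.zeros_like(xg)
        for (cx, cz), amp in zip(centres, amps):
            rho2 = (xg - cx) ** 2 + (zg - cz) ** 2
            out = np.maximum(out, amp * np.clip(1.0 - rho2 / radius**2, 0.0, None))
        return out

    ly = bumps(lx, lz, p.bump_radius, heights)
    lv, lf = _heightfield_solid(
        np.stack([lx, lz], axis=2), ly, plate_y=-p.solid_thickness
    )
    lower = DentalMesh(lv, lf, Arch.lower, watertight=True)

    # ---- upper arch -------------------------------------------------------
    depth_u = p.arch_depth + oj - off
    if depth_u <= bw:
        raise GenerationError("target overjet / class offset flatten the upper arch")
    a_tab_u, _ = _arc_tables(p.arch_width, depth_u)
    half_arc_u = float(a_tab_u[-1])
    a_u = np.linspace(-half_arc_u, half_arc_u, p.n_arc + 1)
    x_u, z_u, nx_u, nz_u, _ = _curve_at(a_u, p.arch_width, depth_u)
    ux = x_u[:, None] + (t[None, :] - 0.5) * bw * nx_u[:, None]
    uz = z_u[:, None] + (t[None, :] - 0.5) * bw * nz_u[:, None]

    uy = sep + bumps(ux, uz, p.fossa_radius, [p.fossa_depth] * len(centres))

    # anterior incisor flange: the front outer part of the upper band dips to
    # the UI height, strictly forward of the lower band plus a safety margin
    flange = oj >= 1.4
    if not flange:
        warnings.warn(
            "target overjet too small for the incisor flange; "
            "UI will sit outside the upper mesh", stacklevel=2,
        )
    li_z = float(p.arch_depth + bw / 2 - off)
    ui = np.array([0.0, -ob, li_z + oj])
    if flange:
        # lower outer-boundary curve near the apex, as z(x)
        xb, zb = lx[:, -1], lz[:, -1]
        near = np.abs(xb) <= 18.0
        srt = np.argsort(xb[near])
        xq, zq = xb[near][srt], zb[near][srt]
        g0 = np.interp(np.clip(ux, xq[0], xq[-1]), xq, zq) + 1.0
        g1 = li_z + oj - 1e-9  # full dip reached at the upper outer edge
        u_frac = np.clip((uz - g0) / np.maximum(g1 - g0, 1e-9), 0.0, 1.0)
        wz = u_frac * u_frac * (3.0 - 2.0 * u_frac)
        wx = np.clip(np.cos(np.clip((np.abs(ux) - 2.0) / 3.0, 0.0, 1.0) * np.pi / 2) ** 2,
                     0.0, 1.0)
        wx[np.abs(ux) <= 2.0] = 1.0
        uy = uy - (sep + ob) * wx * wz

    uv, uf = _heightfield_solid(
        np.stack([ux, uz], axis=2), uy, plate_y=sep + p.solid_thickness
    )
    upper = DentalMesh(uv, uf, Arch.upper, watertight=True)

    # ---- landmarks --------------------------------------------------------
    n_q = p.n_teeth_per_quadrant
    f_can, f_mol = 2.5 / n_q, 5.5 / n_q

    def upper_surface_point(arc_frac: float) -> np.ndarray:
        # nearest upper grid vertex on the centreline at that arc position
        i = int(np.argmin(np.abs(a_u - arc_frac * half_arc_u)))
        j = p.n_band // 2
        return np.array([ux[i, j], uy[i, j], uz[i, j]])

    def molar_points(side: str) -> tuple[np.ndarray, np.ndarray]:
        """(UMcusp, LMcusp): the lower cusp tip at the (class-shifted)
        first-molar bump, the upper cusp above the unshifted molar position,
        so their sagittal difference reads the Angle class offset."""
        sgn = -1.0 if side == "r" else 1.0
        seg = "posterior_right" if side == "r" else "posterior_left"
        a0 = sgn * f_mol * half_arc_l
        cx, cz, _, _, _ = _curve_at(np.array([a0]), p.arch_width, p.arch_depth)
        base = np.array([float(cx[0]), float(cz[0])])
        arcs = patch_arcs.get(seg, np.empty(0))
        if len(arcs):
            shifted = base - (0.0, off)
            idx = int(np.argmin([(c[0] - shifted[0]) ** 2 + (c[1] - shifted[1]) ** 2
                                 for c in centres]))
            lm = np.array([centres[idx][0], heights[idx], centres[idx][1]])
        else:
            lm = np.array([base[0], 0.0, base[1] - off])
        ugrid = np.stack([ux.ravel(), uz.ravel()], axis=1)
        k = int(np.argmin(((ugrid - base) ** 2).sum(axis=1)))
        um = np.array([ux.ravel()[k], uy.ravel()[k], uz.ravel()[k]])
        return um, lm

    um_r, lm_r = molar_points("r")
    um_l, lm_l = molar_points("l")

    landmarks = LandmarkSet(
        UI=ui,
        LI=np.array([0.0, 0.0, li_z]),
        lower_midline=np.array([0.0, 0.0, li_z]),
        canine_r=upper_surface_point(-f_can),
        canine_l=upper_surface_point(+f_can),
        UMcusp_r=um_r,
        UMcusp_l=um_l,
        LMcusp_r=lm_r,
        LMcusp_l=lm_l,
    )

    # ---- feasibility ------------------------------------------------------
    # every bump must sit under the upper band (fossa and patch coverage)
    ug = np.stack([ux.ravel(), uz.ravel()], axis=1)
    for cx, cz in centres:
        d2 = ((ug - (cx, cz)) ** 2).sum(axis=1)
        if d2.min() > p.bump_radius**2:
            raise GenerationError(
                "a designed contact patch falls outside the upper arch footprint"
            )
    hit, _ = meshes_intersect(build_tree(upper), build_tree(lower), return_pairs=False)
    if hit:
        raise GenerationError("arches interpenetrate at the ground-truth occlusion")

    truth = GroundTruth(
        true_occlusion_transform=RigidTransform.identity(
            pivot=landmarks.lower_midline
        ),
        true_contact_count_per_segment=counts,
        true_relationship=jaw_relationship(landmarks),
    )
    return ArchPair(upper=upper, lower=lower, landmarks=landmarks, truth=truth)


# ---------------------------------------------------------------------------
# perturbation and measurement-noise emulation
# ---------------------------------------------------------------------------


def perturb_occlusion(
    upper: DentalMesh,
    lower: DentalMesh,
    max_translation: float,
    max_rotation: float,
    seed: int,
    pivot: np.ndarray | None = None,
    lower_tree: AabbTree | None = None,
    max_draws: int = 100,
) -> RigidTransform:
    """Random collision-free start pose within the given bounds.

    Translation uniform in the ball of radius ``max_translation`` (mm),
    rotations uniform per axis within ±``max_rotation`` (deg), about
    ``pivot`` (default: upper-mesh centroid).  Rejection sampling guarantees
    the displaced pose is collision-free.
    """
    if max_translation < 0 or max_rotation < 0:
        raise ValueError("bounds must be non-negative")
    from .occlusion_setting import pose_collides  # local: avoids module cycle

    rng = np.random.default_rng(seed)
    piv = np.asarray(pivot) if pivot is not None else upper.vertices.mean(axis=0)
    tree = lower_tree if lower_tree is not None else build_tree(lower)
    for _ in range(max_draws):
        if max_translation == 0 and max_rotation == 0:
            return RigidTransform.identity(pivot=piv)
        u = rng.normal(size=3)
        u /= max(np.linalg.norm(u), 1e-12)
        tvec = u * max_translation * rng.uniform() ** (1.0 / 3.0)
        ang = rng.uniform(-max_rotation, max_rotation, size=3)
        T = transform_from_euler(
            piv, roll=ang[2], pitch=ang[0], yaw=ang[1], translation=tvec
        )
        if not pose_collides(upper, T, tree, lower):
            return T
    raise GenerationError("no collision-free displaced pose found")


def observer_noise_tables(
    landmarks: LandmarkSet,
    n_subjects: int = 30,
    sd_per_axis: float = 0.15,
    bias_per_method: dict[str, np.ndarray] | None = None,
    seed: int = 0,
    subject_sd: float = 2.0,
    observers: int = 2,
    timepoints: int = 2,
    methods: tuple[str, ...] = ("M1", "M2", "M3"),
    landmark_names: tuple[str, ...] = ("UI", "UMcusp_r", "UMcusp_l"),
) -> pd.DataFrame:
    """Long-format measurement tables emulating the repeated study design.

    Each of ``n_subjects`` cases gets a true planned landmark position
    (base coordinate + per-case offset with SD ``subject_sd`` per axis);
    every observer/timepoint/method measurement adds i.i.d. Gaussian noise
    (``sd_per_axis``) and a method-level bias vector.  The default bias
    pushes the two virtual methods 0.3 mm anteriorly (+z) relative to the
    conventional method, reproducing the systematic incisal z offset.
    Columns: subject, observer, timepoint, method, landmark, axis, value_mm.
    """
    if n_subjects <= 0 or sd_per_axis < 0 or subject_sd < 0:
        raise ValueError("invalid table parameters")
    if bias_per_method is None:
        bias_per_method = {
            "M1": np.zeros(3),
            "M2": np.array([0.0, 0.0, 0.3]),
            "M3": np.array([0.0, 0.0, 0.3]),
        }
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        case_offset = {
            lm: rng.normal(0.0, subject_sd, size=3) for lm in landmark_names
        }
        for lm in landmark_names:
            base = landmarks[lm] + case_offset[lm]
            for method in methods:
                bias = np.asarray(bias_per_method.get(method, np.zeros(3)))
                for obs in range(1, observers + 1):
                    for tp in range(1, timepoints + 1):
                        meas = base + bias + rng.normal(0.0, sd_per_axis, size=3)
                        for ax, name in enumerate(("x", "y", "z")):
                            rows.append(
                                {
                                    "subject": s + 1,
                                    "observer": obs,
                                    "timepoint": tp,
                                    "method": method,
                                    "landmark": lm,
                                    "axis": name,
                                    "value_mm": float(meas[ax]),
                                }
                            )
    return pd.DataFrame(rows)
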