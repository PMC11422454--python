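"""Setting a surgical occlusion by moving the upper arch.

Two workflows are supported, mirroring clinical practice:

* **manual moves** — translations and roll/pitch/yaw rotations about a
  rotation centre at the lower dental midline, clamped to the last
  collision-free fraction of the requested delta (the virtual equivalent of
  two casts meeting); and
* **spring alignment** — three or more corresponding landmark pairs are
  joined by virtual springs and the upper model is moved rigidly to minimise
  the summed squared spring lengths subject to a no-interpenetration
  constraint.

The spring solver is fit-then-retract-then-refine: the unconstrained
optimum is the closed-form weighted rigid least-squares fit (Kabsch, via
SVD of the weighted cross-covariance); if that pose collides, the motion is
retracted along the approach path (translation lerp, rotation slerp) by
bisection to first contact, then polished by small collision-free
translations/rotations accepted only when they reduce the spring energy.
The collision-free case therefore coincides exactly with the closed-form
optimum, which anchors correctness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .mesh_core import DentalMesh, RigidTransform, transform_from_euler
from .proximity import AabbTree, build_tree, meshes_intersect, points_in_mesh

__all__ = [
    "SpringSet",
    "OcclusionResult",
    "InfeasiblePoseError",
    "DegenerateFitError",
    "rigid_least_squares",
    "springs_align",
    "manual_move",
    "snap_to_contact",
    "pose_collides",
    "minimum_gap",
]

CONTACT_TOL_MM = 1e-3  # poses with min distance in [0, 1e-3] count as touching


class InfeasiblePoseError(RuntimeError):
    """No collision-free pose could be found."""


class DegenerateFitError(ValueError):
    """Spring anchors are collinear or otherwise under-determined."""


@dataclass
class SpringSet:
    """Corresponding point pairs joined by springs.

    ``upper_points`` are attachment points on the upper model (pre-move
    coordinates), ``lower_points`` their targets on the lower model; at
    least three non-collinear pairs make the rigid fit well-posed.
    """

    upper_points: np.ndarray
    lower_points: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.upper_points = np.atleast_2d(
            np.asarray(self.upper_points, dtype=np.float64)
        )
        self.lower_points = np.atleast_2d(
            np.asarray(self.lower_points, dtype=np.float64)
        )
        if self.upper_points.shape != self.lower_points.shape:
            raise ValueError("spring endpoints must pair up")
        if self.weights is None:
            self.weights = np.ones(len(self.upper_points))
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if (self.weights <= 0).any():
            raise ValueError("spring weights must be positive")

    def __len__(self) -> int:
        return len(self.upper_points)

    def energy(self, T: RigidTransform) -> float:
        """Sum of weighted squared spring lengths at pose ``T`` (mm^2)."""
        moved = T.apply(self.upper_points)
        return float(
            np.sum(self.weights * np.sum((moved - self.lower_points) ** 2, axis=1))
        )

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "pairs": [
                    {"upper": u.tolist(), "lower": l.tolist(), "weight": float(w)}
                    for u, l, w in zip(
                        self.upper_points, self.lower_points, self.weights
                    )
                ]
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "SpringSet":
        import json

        d = json.loads(text)
        pairs = d["pairs"]
        return SpringSet(
            upper_points=[p["upper"] for p in pairs],
            lower_points=[p["lower"] for p in pairs],
            weights=[p.get("weight", 1.0) for p in pairs],
        )


@dataclass
class OcclusionResult:
    transform: RigidTransform
    residual_spring_energy: float
    collision_free: bool
    iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# closed-form rigid fit
# ---------------------------------------------------------------------------


def rigid_least_squares(
    src: np.ndarray, dst: np.ndarray, weights: np.ndarray | None = None
) -> RigidTransform:
    """Weighted rigid least-squares fit (Kabsch): argmin Σ wᵢ‖R sᵢ + t − dᵢ‖².

    Raises :class:`DegenerateFitError` for fewer than three pairs or
    collinear anchors.
    """
    src = np.atleast_2d(np.asarray(src, dtype=np.float64))
    dst = np.atleast_2d(np.asarray(dst, dtype=np.float64))
    w = np.ones(len(src)) if weights is None else np.asarray(weights, dtype=np.float64)
    if len(src) < 3:
        raise DegenerateFitError("need at least three spring pairs")
    w = w / w.sum()
    mu_s = w @ src
    mu_d = w @ dst
    cs = src - mu_s
    cd = dst - mu_d
    cov = (cd * w[:, None]).T @ cs
    # collinearity: centred anchors with rank < 2 leave a free rotation
    if np.linalg.matrix_rank(cs, tol=1e-9 * max(1.0, np.abs(cs).max())) < 2:
        raise DegenerateFitError("spring anchors are collinear")
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, 1.0, d]) @ vt
    t = mu_d - r @ mu_s
    return RigidTransform(r, t, np.zeros(3))


# ---------------------------------------------------------------------------
# collision predicates
# ---------------------------------------------------------------------------


def pose_collides(
    upper: DentalMesh, T: RigidTransform, lower_tree: AabbTree, lower: DentalMesh | None = None
) -> bool:
    """True if the transformed upper mesh interpenetrates the lower mesh.

    Proper triangle crossings are checked tree-against-tree; a cheap
    containment probe guards the (unphysical) fully-swallowed case.
    """
    moved = T.apply(upper.vertices)
    up_tree = AabbTree(moved[upper.faces])
    hit, _ = meshes_intersect(up_tree, lower_tree, return_pairs=False)
    if hit:
        return True
    # containment probes: one vertex of each mesh against the other
    if points_in_mesh(moved[:1], lower_tree)[0]:
        return True
    if lower is not None and len(lower.vertices):
        if points_in_mesh(lower.vertices[:1], up_tree)[0]:
            return True
    return False


def minimum_gap(upper: DentalMesh, T: RigidTransform, lower_tree: AabbTree) -> float:
    """Minimum unsigned surface distance sampled at transformed upper vertices."""
    moved = T.apply(upper.vertices)
    return min(lower_tree.closest_point(p)[0] for p in moved)


# ---------------------------------------------------------------------------
# interpolation along the approach path
# ---------------------------------------------------------------------------


def _lerp_transform(T0: RigidTransform, T1: RigidTransform, s: float) -> RigidTransform:
    """Pose at fraction ``s`` of the screw-free path T0 -> T1 (lerp + slerp)."""
    if s >= 1.0:
        return T1
    if s <= 0.0:
        return T0
    rots = Rotation.from_matrix(np.stack([T0.rotation, T1.rotation]))
    r = Slerp([0.0, 1.0], rots)(s).as_matrix()
    c = (1.0 - s) * T0.offset + s * T1.offset
    return RigidTransform(r, c, np.zeros(3))


_SCAN_STEP_MM = 0.4  # max displacement between path samples (anti-tunnelling)


def _bisect_free(
    upper: DentalMesh,
    lower_tree: AabbTree,
    pose_at,
    motion_mm: float,
    lower: DentalMesh | None = None,
    tol_mm: float = 1e-4,
) -> float:
    """Largest s in [0, 1] such that the path [0, s] is collision-free.

    The path is first scanned at steps bounded by ``_SCAN_STEP_MM`` of
    displacement (a plain bisection could tunnel through thin geometry),
    then the first-contact parameter is bisected to ``tol_mm`` of motion.
    s = 0 must be collision-free.
    """
    if pose_collides(upper, pose_at(0.0), lower_tree, lower):
        raise InfeasiblePoseError("start pose already collides")
    if motion_mm <= 0:
        return 1.0
    n = max(1, int(np.ceil(motion_mm / _SCAN_STEP_MM)))
    lo = 0.0
    hi = None
    for k in range(1, n + 1):
        s = k / n
        if pose_collides(upper, pose_at(s), lower_tree, lower):
            hi = s
            break
        lo = s
    if hi is None:
        return 1.0
    tol_s = max(tol_mm / motion_mm, 1e-12)
    while hi - lo > tol_s:
        mid = 0.5 * (lo + hi)
        if pose_collides(upper, pose_at(mid), lower_tree, lower):
            hi = mid
        else:
            lo = mid
    return lo


def _mesh_radius(mesh: DentalMesh) -> float:
    c = mesh.vertices.mean(axis=0)
    return float(np.sqrt(((mesh.vertices - c) ** 2).sum(axis=1).max()))


# ---------------------------------------------------------------------------
# spring alignment
# ---------------------------------------------------------------------------


def springs_align(
    upper: DentalMesh,
    lower: DentalMesh,
    springs: SpringSet,
    tol: float = 1e-3,
    max_iter: int = 200,
    check_collisions: bool = True,
    lower_tree: AabbTree | None = None,
) -> OcclusionResult:
    """Move the upper model to minimise spring energy without interpenetration.

    With ``check_collisions=False`` (or when the optimum is collision-free)
    the result is exactly the closed-form weighted rigid least-squares fit.
    Refinement steps: translations 0.05 mm and rotations 0.1 deg, halved on
    rejection down to 1e-3 mm / 1e-3 deg; a step is accepted only if it is
    collision-free and strictly decreases the energy.  Deterministic.
    """
    fit = rigid_least_squares(springs.upper_points, springs.lower_points, springs.weights)
    if not check_collisions:
        return OcclusionResult(fit, springs.energy(fit), True, 0, True)

    tree = lower_tree if lower_tree is not None else build_tree(lower)
    if not pose_collides(upper, fit, tree, lower):
        return OcclusionResult(fit, springs.energy(fit), True, 0, True)

    # retract along the approach from the identity (current) pose
    ident = RigidTransform.identity()
    angle = float(Rotation.from_matrix(fit.rotation).magnitude())
    motion = float(np.linalg.norm(fit.offset)) + angle * _mesh_radius(upper)
    s = _bisect_free(
        upper, tree, lambda q: _lerp_transform(ident, fit, q), motion, lower
    )
    current = _lerp_transform(ident, fit, s)
    energy = springs.energy(current)

    # projected local refinement about the spring centroid
    pivot = springs.upper_points.mean(axis=0)
    step_t, step_r = 0.05, 0.1
    iterations = 0
    converged = False
    while iterations < max_iter:
        iterations += 1
        best = None
        moves = []
        for axis in range(3):
            for sgn in (+1.0, -1.0):
                dt = np.zeros(3)
                dt[axis] = sgn * step_t
                moves.append(RigidTransform(np.eye(3), dt, np.zeros(3)))
                ang = [0.0, 0.0, 0.0]
                ang[axis] = sgn * step_r
                moves.append(
                    transform_from_euler(
                        current.apply(pivot), roll=ang[2], pitch=ang[0], yaw=ang[1]
                    )
                )
        for mv in moves:
            cand = mv.compose(current)
            e = springs.energy(cand)
            if e < energy - 1e-15 and (best is None or e < best[0]):
                if not pose_collides(upper, cand, tree, lower):
                    best = (e, cand)
        if best is None:
            step_t *= 0.5
            step_r *= 0.5
            if step_t < 1e-3 and step_r < 1e-3:
                converged = True
                break
            continue
        if energy - best[0] < tol**2:
            energy, current = best
            converged = True
            break
        energy, current = best

    return OcclusionResult(current, energy, True, iterations, converged)


# ---------------------------------------------------------------------------
# manual moves
# ---------------------------------------------------------------------------


def manual_move(
    state: RigidTransform,
    upper: DentalMesh,
    lower: DentalMesh,
    pivot: np.ndarray,
    roll: float = 0.0,
    pitch: float = 0.0,
    yaw: float = 0.0,
    translation=(0.0, 0.0, 0.0),
    lower_tree: AabbTree | None = None,
) -> tuple[RigidTransform, bool, float]:
    """Apply a translational/rotational delta about the rotation centre.

    If the full delta would interpenetrate, the move is scaled back by
    bisection along the delta to the largest collision-free fraction
    (clamp-to-contact).  Returns (new_state, clamped, applied_fraction).
    """
    tree = lower_tree if lower_tree is not None else build_tree(lower)
    translation = np.asarray(translation, dtype=np.float64)

    def pose_at(f: float) -> RigidTransform:
        delta = transform_from_euler(
            pivot, roll=f * roll, pitch=f * pitch, yaw=f * yaw,
            translation=f * translation,
        )
        return delta.compose(state)

    if roll == pitch == yaw == 0.0 and not translation.any():
        return state, False, 1.0
    moved = state.apply(upper.vertices)
    r_piv = float(np.sqrt(((moved - np.asarray(pivot)) ** 2).sum(axis=1).max()))
    motion = float(np.linalg.norm(translation)) + np.deg2rad(
        abs(roll) + abs(pitch) + abs(yaw)
    ) * r_piv
    f = _bisect_free(upper, tree, pose_at, motion, lower)
    return pose_at(f), f < 1.0, f


def snap_to_contact(
    upper: DentalMesh,
    lower: DentalMesh,
    direction: np.ndarray,
    max_travel: float,
    state: RigidTransform | None = None,
    tol: float = 1e-4,
    lower_tree: AabbTree | None = None,
) -> RigidTransform:
    """Translate the upper model along ``direction`` until just before contact.

    Pure translation; bisection to ``tol`` (mm).  Raises
    :class:`InfeasiblePoseError` if the meshes already collide.
    """
    d = np.asarray(direction, dtype=np.float64)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must be non-zero")
    d = d / n
    tree = lower_tree if lower_tree is not None else build_tree(lower)
    base = state if state is not None else RigidTransform.identity()

    def pose_at(f: float) -> RigidTransform:
        step = RigidTransform(np.eye(3), f * max_travel * d, np.zeros(3))
        return step.compose(base)

    f = _bisect_free(upper, tree, pose_at, max_travel, lower, tol_mm=tol)
    return pose_at(f)
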