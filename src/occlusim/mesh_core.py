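"""Dental mesh and landmark I/O, the patient coordinate frame, and rigid
transforms.

All geometry lives in a fixed patient frame in millimetres:

* x — transverse: patient's right is negative, left is positive;
* y — vertical: down is negative, up is positive;
* z — sagittal: back is negative, forward is positive.

Upper and lower dentitions are triangle meshes (STL in, STL out) assumed to
be already registered to this frame.  A :class:`RigidTransform` is a proper
rotation plus translation, with an explicit pivot point about which rotation
parameters are interpreted (clinically: the lower dental midline).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import trimesh

__all__ = [
    "Arch",
    "PatientFrame",
    "DentalMesh",
    "LandmarkSet",
    "RigidTransform",
    "MeshFormatError",
    "MeshValidationError",
    "load_mesh",
    "save_mesh",
    "apply_transform",
    "transform_from_euler",
    "weld_vertices",
    "load_landmarks",
    "save_landmarks",
]

WELD_TOLERANCE_MM = 1e-6
DEGENERATE_AREA_MM2 = 1e-12
ROTATION_TOL = 1e-9


class MeshFormatError(ValueError):
    """Raised when an input file cannot be parsed as a triangle mesh."""


class MeshValidationError(ValueError):
    """Raised when a mesh or transform fails its validity contract."""


class Arch(str, Enum):
    upper = "upper"
    lower = "lower"


class PatientFrame:
    """Axis semantics of the patient coordinate frame (mm).

    Purely descriptive: every module interprets raw coordinates in this
    right-handed frame, no conversion is ever applied.
    """

    AXES = ("x", "y", "z")
    DESCRIPTION = {
        "x": "transverse: right (-) / left (+)",
        "y": "vertical: down (-) / up (+)",
        "z": "sagittal: back (-) / forward (+)",
    }


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


@dataclass
class DentalMesh:
    """Triangle mesh of one dental arch in the patient frame (mm)."""

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int64
    arch: Arch
    watertight: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be (m, 3)")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshValidationError("face indices out of range")
        if not np.isfinite(self.vertices).all():
            raise MeshValidationError("non-finite vertex coordinates")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> np.ndarray:
        """Axis-aligned bounding box as a (2, 3) [min; max] array."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def vertex_adjacency_edges(self) -> np.ndarray:
        """Unique undirected vertex-pair edges of the face graph, (e, 2)."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def copy(self) -> "DentalMesh":
        return DentalMesh(
            self.vertices.copy(), self.faces.copy(), self.arch, self.watertight
        )


def weld_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOLERANCE_MM
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol`` (grid quantisation) and re-index."""
    if len(vertices) == 0:
        return vertices, faces
    keys = np.round(np.asarray(vertices, dtype=np.float64) / tol).astype(np.int64)
    _, first, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    welded = np.asarray(vertices, dtype=np.float64)[first]
    return welded, inverse[faces]


def _clean(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vertices, faces = weld_vertices(vertices, faces)
    if len(faces):
        # drop faces with repeated indices or sub-threshold area
        distinct = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        )
        t = vertices[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )
        faces = faces[distinct & (areas > DEGENERATE_AREA_MM2)]
    # drop unreferenced vertices
    if len(faces):
        used = np.unique(faces)
        remap = -np.ones(len(vertices), dtype=np.int64)
        remap[used] = np.arange(len(used))
        vertices, faces = vertices[used], remap[faces]
    else:
        vertices = vertices[:0]
    return vertices, faces


def load_mesh(path: str | Path, arch: Arch | str) -> DentalMesh:
    """Load a binary or ASCII STL file, weld, validate and report watertightness.

    Raises :class:`MeshFormatError` for unreadable files and
    :class:`MeshValidationError` when nothing remains after cleaning.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    try:
        tm = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise MeshFormatError(f"cannot parse STL {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshFormatError(f"no geometry in {path}")
        tm = trimesh.util.concatenate(geoms)
    vertices, faces = _clean(np.asarray(tm.vertices), np.asarray(tm.faces))
    if len(faces) == 0:
        raise MeshValidationError(f"empty mesh after cleaning: {path}")
    check = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    return DentalMesh(vertices, faces, Arch(arch), watertight=bool(check.is_watertight))


def save_mesh(mesh: DentalMesh, path: str | Path, ascii: bool = False) -> None:
    """Write a mesh as binary (default) or ASCII STL."""
    tm = mesh.to_trimesh()
    path = Path(path)
    if ascii:
        data = trimesh.exchange.stl.export_stl_ascii(tm)
        path.write_text(data)
    else:
        tm.export(str(path), file_type="stl")


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------


def _axis_rotation(axis: str, degrees: float) -> np.ndarray:
    a = np.deg2rad(degrees)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=np.float64)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=np.float64)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=np.float64)
    raise ValueError(axis)


@dataclass
class RigidTransform:
    """Proper rigid motion: ``p -> R (p - pivot) + pivot + t``.

    ``pivot`` is the point about which the rotation parameters are read
    (the lower dental midline in the clinical workflow); it does not change
    the group structure, only the parameterisation.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pivot: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.pivot = np.asarray(self.pivot, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise MeshValidationError("rotation determinant must be +1")
        if np.abs(self.rotation @ self.rotation.T - np.eye(3)).max() > 1e-6:
            raise MeshValidationError("rotation matrix must be orthonormal")

    # -- group operations ---------------------------------------------------

    @staticmethod
    def identity(pivot: Iterable[float] | None = None) -> "RigidTransform":
        return RigidTransform(
            np.eye(3), np.zeros(3), np.zeros(3) if pivot is None else np.asarray(pivot)
        )

    @property
    def offset(self) -> np.ndarray:
        """Effective translation c of the map p -> R p + c."""
        return self.pivot - self.rotation @ self.pivot + self.translation

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        out = p @ self.rotation.T + self.offset
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (``other`` applied first); pivot at origin."""
        r = self.rotation @ other.rotation
        c = self.rotation @ other.offset + self.offset
        return RigidTransform(_orthonormalize(r), c, np.zeros(3))

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform(r, -(r @ self.offset), np.zeros(3))

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.offset
        return m

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "matrix": self.matrix().reshape(-1).tolist(),  # 4x4 row-major
                "pivot": self.pivot.tolist(),
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "RigidTransform":
        d = json.loads(text)
        m = np.asarray(d["matrix"], dtype=np.float64).reshape(4, 4)
        pivot = np.asarray(d.get("pivot", (0.0, 0.0, 0.0)), dtype=np.float64)
        r = m[:3, :3]
        # matrix stores the effective offset; convert back to pivot form
        t = m[:3, 3] - (pivot - r @ pivot)
        return RigidTransform(r, t, pivot)


def _orthonormalize(r: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) (guards compose round-off)."""
    u, _, vt = np.linalg.svd(r)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def apply_transform(mesh: DentalMesh, T: RigidTransform) -> DentalMesh:
    """Return a new mesh with every vertex mapped through ``T``."""
    return replace(mesh, vertices=T.apply(mesh.vertices))


def transform_from_euler(
    pivot: Iterable[float],
    roll: float = 0.0,
    pitch: float = 0.0,
    yaw: float = 0.0,
    translation: Iterable[float] = (0.0, 0.0, 0.0),
) -> RigidTransform:
    """Build a transform from clinical rotation parameters (degrees) about a pivot.

    Convention: roll is rotation about the sagittal z-axis, pitch about the
    transverse x-axis, yaw about the vertical y-axis, applied intrinsically
    in the order roll -> pitch -> yaw, i.e. R = Rz(roll) Rx(pitch) Ry(yaw);
    the translation (mm) is applied after rotation.
    """
    for v in (roll, pitch, yaw):
        if not np.isfinite(v):
            raise MeshValidationError("angles must be finite")
    r = _axis_rotation("z", roll) @ _axis_rotation("x", pitch) @ _axis_rotation("y", yaw)
    return RigidTransform(r, np.asarray(translation, dtype=np.float64), np.asarray(pivot))


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

UPPER_LANDMARKS = ("UI", "UMcusp_r", "UMcusp_l", "canine_r", "canine_l")
LOWER_LANDMARKS = ("LI", "LMcusp_r", "LMcusp_l", "lower_midline")
LANDMARK_NAMES = UPPER_LANDMARKS + LOWER_LANDMARKS


@dataclass
class LandmarkSet:
    """Named dental landmarks (mm, patient frame).

    UI / LI: upper / lower incisal points; UMcusp / LMcusp: mesio-buccal
    first-molar cusp tips (right/left); canine_r/l: upper canine cusp tips
    (segment boundaries); lower_midline: rotation-centre point on the lower
    dental midline.
    """

    UI: np.ndarray | None = None
    LI: np.ndarray | None = None
    UMcusp_r: np.ndarray | None = None
    UMcusp_l: np.ndarray | None = None
    LMcusp_r: np.ndarray | None = None
    LMcusp_l: np.ndarray | None = None
    canine_r: np.ndarray | None = None
    canine_l: np.ndarray | None = None
    lower_midline: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in LANDMARK_NAMES:
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.float64).reshape(3)
                if not np.isfinite(v).all():
                    raise MeshValidationError(f"landmark {name} not finite")
                setattr(self, name, v)

    def __getitem__(self, name: str) -> np.ndarray:
        v = getattr(self, name)
        if v is None:
            raise KeyError(f"landmark {name} missing")
        return v

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise MeshValidationError(f"missing landmarks: {', '.join(missing)}")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            n: getattr(self, n) for n in LANDMARK_NAMES if getattr(self, n) is not None
        }

    def transformed(self, T: RigidTransform, which: str = "upper") -> "LandmarkSet":
        """Apply ``T`` to the upper (default), lower, or all landmarks."""
        names = {
            "upper": UPPER_LANDMARKS,
            "lower": LOWER_LANDMARKS,
            "all": LANDMARK_NAMES,
        }[which]
        out = {n: v.copy() for n, v in self.as_dict().items()}
        for n in names:
            if n in out:
                out[n] = T.apply(out[n])
        return LandmarkSet(**out)

    def validate_against(self, mesh: DentalMesh, which: str = "upper") -> bool:
        """Warn if landmarks of one arch fall outside that mesh's bounding box."""
        names = UPPER_LANDMARKS if which == "upper" else LOWER_LANDMARKS
        lo, hi = mesh.bounds()
        ok = True
        for n in names:
            v = getattr(self, n)
            if v is None:
                continue
            if (v < lo - 1e-9).any() or (v > hi + 1e-9).any():
                warnings.warn(
                    f"landmark {n} lies outside the {which} mesh bounding box",
                    stacklevel=2,
                )
                ok = False
        return ok


def load_landmarks(path: str | Path) -> LandmarkSet:
    """Read landmarks from CSV (columns name,x,y,z) or JSON ({name: [x,y,z]})."""
    path = Path(path)
    text = path.read_text()
    coords: dict[str, list[float]] = {}
    if path.suffix.lower() == ".json":
        coords = json.loads(text)
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.lower().startswith("name"):
                continue
            parts = line.split(",")
            coords[parts[0].strip()] = [float(p) for p in parts[1:4]]
    known = {k: v for k, v in coords.items() if k in LANDMARK_NAMES}
    return LandmarkSet(**known)


def save_landmarks(
    landmarks: LandmarkSet | Mapping[str, np.ndarray], path: str | Path
) -> None:
    d = landmarks.as_dict() if isinstance(landmarks, LandmarkSet) else dict(landmarks)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps({k: np.asarray(v).tolist() for k, v in d.items()}, indent=2)
        )
    else:
        lines = ["name,x,y,z"]
        lines += [f"{k},{v[0]:.9g},{v[1]:.9g},{v[2]:.9g}" for k, v in d.items()]
        path.write_text("\n".join(lines) + "\n")
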