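"""Signed inter-arch distance field, contact extraction and arch segmentation.

The occlusogram is the per-vertex map of minimal distances from the upper
dentition to the lower dental surface.  Distances are sampled at the upper
mesh vertices; the sign is negative where a vertex lies inside the closed
lower surface (interference — physically impossible with real casts, so its
presence flags an invalid virtual occlusion).

An *occlusal contact* is a coherent surface area whose distance to the lower
arch is between 0 and 0.5 mm.  Coherence is operationalised as a connected
component of the upper-mesh vertex adjacency graph restricted to contact
vertices.  Contacts are counted per dental-arch segment: anterior (canine to
canine), posterior right and posterior left (first premolar to second molar
on each side), with regions assigned to the segment of their centroid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .mesh_core import DentalMesh, LandmarkSet
from .proximity import AabbTree, build_tree, points_in_mesh

__all__ = [
    "DistanceField",
    "ContactParams",
    "ContactRegion",
    "ContactReport",
    "ArchSegmentation",
    "SEGMENTS",
    "compute_distance_field",
    "segment_arch",
    "extract_contact_regions",
    "summarize_contacts",
    "export_field_csv",
    "export_field_ply",
]

SEGMENTS = ("anterior", "posterior_right", "posterior_left")

CONTACT_THRESHOLD_MM = 0.5  # "0.5 mm or less" contact definition


@dataclass
class DistanceField:
    """Per-upper-vertex signed distance to the lower surface (mm).

    ``clamp_max`` is a display ceiling only (the occlusogram colour range
    runs 0 .. +0.5 mm); stored values are unclamped.
    """

    values: np.ndarray
    clamp_max: float = CONTACT_THRESHOLD_MM
    sign_reliable: bool = True

    @property
    def interference_present(self) -> bool:
        return bool((self.values < 0).any())

    def clamped(self) -> np.ndarray:
        return np.minimum(self.values, self.clamp_max)


@dataclass
class ContactParams:
    contact_threshold: float = CONTACT_THRESHOLD_MM
    min_region_vertices: int = 1

    def __post_init__(self) -> None:
        if self.contact_threshold <= 0:
            raise ValueError("contact_threshold must be positive")


@dataclass
class ContactRegion:
    vertex_ids: np.ndarray
    area_mm2: float
    centroid: np.ndarray
    segment: str | None = None


@dataclass
class ContactReport:
    regions: list[ContactRegion]
    counts: dict[str, int] = field(default_factory=dict)
    interference_present: bool = False

    @property
    def n_contacts(self) -> int:
        return len(self.regions)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_contacts": self.n_contacts,
                "interference_present": self.interference_present,
                "counts": self.counts,
                "regions": [
                    {
                        "vertex_ids": r.vertex_ids.tolist(),
                        "area_mm2": r.area_mm2,
                        "centroid": r.centroid.tolist(),
                        "segment": r.segment,
                    }
                    for r in self.regions
                ],
            },
            indent=2,
        )


@dataclass
class ArchSegmentation:
    """Per-upper-vertex segment label (index into SEGMENTS)."""

    labels: np.ndarray  # (n,) of strings from SEGMENTS

    def counts(self) -> dict[str, int]:
        return {s: int((self.labels == s).sum()) for s in SEGMENTS}


# ---------------------------------------------------------------------------


def compute_distance_field(
    upper: DentalMesh,
    lower: DentalMesh,
    lower_tree: AabbTree | None = None,
) -> DistanceField:
    """Signed minimal distance from every upper vertex to the lower surface.

    The unsigned part is the exact point-to-surface distance; the sign is
    assigned by the ray-parity inside test against the (watertight) lower
    mesh.  For a non-watertight lower mesh the signs are still computed but
    flagged unreliable.
    """
    tree = lower_tree if lower_tree is not None else build_tree(lower)
    n = upper.n_vertices
    d = np.empty(n)
    for i, p in enumerate(upper.vertices):
        d[i] = tree.closest_point(p)[0]
    inside = points_in_mesh(upper.vertices, tree)
    d[inside] *= -1.0
    return DistanceField(values=d, sign_reliable=lower.watertight)


def segment_arch(
    upper: DentalMesh, landmarks: LandmarkSet, method: str = "tangent"
) -> ArchSegmentation:
    """Label every upper vertex anterior / posterior_right / posterior_left.

    ``tangent`` (default): a boundary plane through each canine cusp tip,
    perpendicular to the local arch tangent (estimated from the incisal
    point towards the ipsilateral molar cusp, projected to the occlusal
    plane); a vertex is anterior iff it lies on the incisal side of both
    planes.  ``zplane``: simpler sagittal-coordinate threshold at the mean
    canine z.  Posterior vertices split right/left at the mid-sagittal plane
    through the lower midline (or UI).
    """
    landmarks.require("canine_r", "canine_l")
    v = upper.vertices
    if method == "tangent":
        landmarks.require("UI", "UMcusp_r", "UMcusp_l")
        ui = landmarks["UI"]
        anterior = np.ones(len(v), dtype=bool)
        for canine, molar in (
            (landmarks["canine_r"], landmarks["UMcusp_r"]),
            (landmarks["canine_l"], landmarks["UMcusp_l"]),
        ):
            tangent = molar - ui
            tangent[1] = 0.0  # occlusal-plane projection
            norm = np.linalg.norm(tangent)
            if norm < 1e-9:
                raise ValueError("degenerate arch tangent")
            tangent /= norm
            side = np.sign(np.dot(ui - canine, tangent)) or 1.0
            anterior &= ((v - canine) @ tangent) * side >= 0.0
    elif method == "zplane":
        z_cut = 0.5 * (landmarks["canine_r"][2] + landmarks["canine_l"][2])
        anterior = v[:, 2] >= z_cut
    else:
        raise ValueError(f"unknown segmentation method: {method}")

    mid = landmarks.lower_midline if landmarks.lower_midline is not None else landmarks["UI"]
    labels = np.where(
        anterior,
        "anterior",
        np.where(v[:, 0] < mid[0], "posterior_right", "posterior_left"),
    ).astype(object)
    return ArchSegmentation(labels=np.asarray(labels, dtype=object))


def _vertex_areas(mesh: DentalMesh) -> np.ndarray:
    areas = mesh.face_areas()
    va = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(va, mesh.faces[:, k], areas / 3.0)
    return va


def extract_contact_regions(
    fieldd: DistanceField,
    upper: DentalMesh,
    params: ContactParams | None = None,
    segmentation: ArchSegmentation | None = None,
) -> ContactReport:
    """Connected contact regions: components of the vertex adjacency graph
    restricted to vertices with 0 <= d <= threshold (inclusive at the
    threshold).  Interpenetrating vertices (d < 0) are interference and are
    never part of a contact region.
    """
    params = params or ContactParams()
    d = fieldd.values
    if len(d) != upper.n_vertices:
        raise ValueError("field was not computed on this mesh")
    mask = (d >= 0.0) & (d <= params.contact_threshold)
    report = ContactReport(
        regions=[], counts={s: 0 for s in SEGMENTS},
        interference_present=fieldd.interference_present,
    )
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return report

    remap = -np.ones(upper.n_vertices, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    edges = upper.vertex_adjacency_edges()
    keep = mask[edges[:, 0]] & mask[edges[:, 1]]
    e = remap[edges[keep]]
    graph = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(len(idx), len(idx))
    )
    n_comp, comp = connected_components(graph, directed=False)

    vertex_area = _vertex_areas(upper)
    for c in range(n_comp):
        vids = idx[comp == c]
        if len(vids) < params.min_region_vertices:
            continue
        centroid = upper.vertices[vids].mean(axis=0)
        region = ContactRegion(
            vertex_ids=vids,
            area_mm2=float(vertex_area[vids].sum()),
            centroid=centroid,
        )
        if segmentation is not None:
            # a region spanning a boundary is assigned whole: the label of
            # the member vertex closest to the region centroid decides
            nearest = vids[
                np.argmin(((upper.vertices[vids] - centroid) ** 2).sum(axis=1))
            ]
            region.segment = str(segmentation.labels[nearest])
            report.counts[region.segment] += 1
        report.regions.append(region)
    return report


def summarize_contacts(report: ContactReport) -> dict:
    """Per-segment counts and percentage distribution (sums to 100)."""
    counts = {s: report.counts.get(s, 0) for s in SEGMENTS}
    total = sum(counts.values())
    if report.n_contacts and total != report.n_contacts:
        # regions without segmentation: count them under their own key
        counts = dict(counts)
        counts["unsegmented"] = report.n_contacts - total
        total = report.n_contacts
    empty = total == 0
    pct = {
        s: (0.0 if empty else 100.0 * c / total) for s, c in counts.items()
    }
    return {
        "counts": counts,
        "total": total,
        "percent": pct,
        "empty": empty,
        "interference_present": report.interference_present,
    }


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def export_field_csv(
    fieldd: DistanceField,
    upper: DentalMesh,
    path: str | Path,
    segmentation: ArchSegmentation | None = None,
) -> None:
    lines = ["vertex_id,x,y,z,signed_distance,segment"]
    labels = segmentation.labels if segmentation is not None else None
    for i, (v, d) in enumerate(zip(upper.vertices, fieldd.values)):
        seg = labels[i] if labels is not None else ""
        lines.append(f"{i},{v[0]:.6f},{v[1]:.6f},{v[2]:.6f},{d:.6f},{seg}")
    Path(path).write_text("\n".join(lines) + "\n")


def export_field_ply(fieldd: DistanceField, upper: DentalMesh, path: str | Path) -> None:
    """ASCII PLY with a per-vertex ``signed_distance`` scalar property."""
    n, m = upper.n_vertices, upper.n_faces
    head = [
        "ply",
        "format ascii 1.0",
        "comment occlusogram signed distance field (mm)",
        f"element vertex {n}",
        "property float x",
        "property float y",
        "property float z",
        "property float signed_distance",
        f"element face {m}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    body = [
        f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {d:.6f}"
        for v, d in zip(upper.vertices, fieldd.values)
    ]
    faces = [f"3 {f[0]} {f[1]} {f[2]}" for f in upper.faces]
    Path(path).write_text("\n".join(head + body + faces) + "\n")
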