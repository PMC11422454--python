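"""Shared fixtures: boxes, plates, small random meshes, and one default
synthetic arch pair (session-scoped, reused by the occlusogram / recovery /
acceptance tests)."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from occlusim import (
    ArchParams,
    ContactParams,
    build_tree,
    compute_distance_field,
    extract_contact_regions,
    generate_arch_pair,
    segment_arch,
)
from occlusim.mesh_core import Arch, DentalMesh


def make_box(center, extents, arch=Arch.lower) -> DentalMesh:
    b = trimesh.creation.box(extents=extents)
    b.apply_translation(center)
    return DentalMesh(
        np.asarray(b.vertices), np.asarray(b.faces), arch, watertight=True
    )


def make_plates(gap: float) -> tuple[DentalMesh, DentalMesh]:
    """Plates: lower top surface at y=0, upper bottom at y=gap.

    The upper footprint (8x8) is smaller than the lower (10x10) so that
    upper bottom vertices project onto the lower top face interior.
    """
    upper = make_box((0.0, gap + 0.5, 0.0), (8.0, 1.0, 8.0), Arch.upper)
    lower = make_box((0.0, -0.75, 0.0), (10.0, 1.5, 10.0), Arch.lower)
    return upper, lower


def random_soup(rng: np.random.Generator, n_tri: int, scale: float = 1.0,
                center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Random triangle soup (n, 3, 3) — valid AABB-tree input, not a manifold."""
    anchors = rng.uniform(-scale, scale, size=(n_tri, 1, 3)) + np.asarray(center)
    tris = anchors + rng.uniform(-0.4 * scale, 0.4 * scale, size=(n_tri, 3, 3))
    return tris


def small_closed_mesh(rng: np.random.Generator, center=(0, 0, 0),
                      radius: float = 1.0) -> DentalMesh:
    """Watertight bumpy sphere with <= 200 triangles."""
    s = trimesh.creation.icosphere(subdivisions=1, radius=radius)
    v = np.asarray(s.vertices)
    v = v * (1.0 + 0.15 * rng.standard_normal((len(v), 1)))
    v = v + np.asarray(center)
    return DentalMesh(v, np.asarray(s.faces), Arch.lower, watertight=True)


@pytest.fixture(scope="session")
def arch_pair():
    return generate_arch_pair(ArchParams())


@pytest.fixture(scope="session")
def arch_field(arch_pair):
    """Distance field of the default pair at ground truth."""
    return compute_distance_field(arch_pair.upper, arch_pair.lower)


@pytest.fixture(scope="session")
def arch_report(arch_pair, arch_field):
    seg = segment_arch(arch_pair.upper, arch_pair.landmarks)
    return extract_contact_regions(
        arch_field, arch_pair.upper, ContactParams(), seg
    )


@pytest.fixture(scope="session")
def lower_tree(arch_pair):
    return build_tree(arch_pair.lower)
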