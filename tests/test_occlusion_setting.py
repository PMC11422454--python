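"""Spring alignment, collision-clamped manual moves, snap-to-contact."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_plates
from occlusim import apply_transform
from occlusim.mesh_core import RigidTransform, transform_from_euler
from occlusim.occlusion_setting import (
    DegenerateFitError,
    InfeasiblePoseError,
    SpringSet,
    manual_move,
    minimum_gap,
    rigid_least_squares,
    snap_to_contact,
    springs_align,
)
from occlusim.proximity import build_tree, meshes_intersect
from occlusim.synthetic_arch import perturb_occlusion


class TestRigidLeastSquares:
    @pytest.mark.parametrize("seed", range(50))
    def test_recovers_known_transform(self, seed):
        """Closed-form fit equals the generating transform on clean pairs."""
        rng = np.random.default_rng(seed)
        src = rng.normal(size=(rng.integers(3, 12), 3)) * 10
        T = transform_from_euler(
            rng.normal(size=3),
            *rng.uniform(-40, 40, 3),
            translation=rng.normal(size=3) * 8,
        )
        dst = T.apply(src)
        w = rng.uniform(0.2, 3.0, len(src))
        fit = rigid_least_squares(src, dst, w)
        np.testing.assert_allclose(fit.apply(src), dst, atol=1e-6)

    def test_matches_scipy_align_vectors_on_noisy_pairs(self):
        """Independent oracle: scipy's weighted Wahba solution."""
        rng = np.random.default_rng(99)
        src = rng.normal(size=(8, 3)) * 5
        dst = src @ Rotation.from_euler("zyx", [20, -10, 5], degrees=True).as_matrix().T
        dst += rng.normal(scale=0.1, size=dst.shape) + (1.0, -2.0, 0.5)
        w = rng.uniform(0.5, 2.0, 8)
        fit = rigid_least_squares(src, dst, w)
        wn = w / w.sum()
        mu_s, mu_d = wn @ src, wn @ dst
        rot, _ = Rotation.align_vectors(dst - mu_d, src - mu_s, weights=w)
        np.testing.assert_allclose(fit.rotation, rot.as_matrix(), atol=1e-8)

    def test_collinear_anchors_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateFitError):
            rigid_least_squares(src, src + 1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DegenerateFitError):
            rigid_least_squares(np.zeros((2, 3)), np.ones((2, 3)))


class TestSpringsAlign:
    def test_satisfied_springs_give_identity(self):
        upper, lower = make_plates(gap=3.0)
        anchors = np.array([[-4.0, 3.5, -4.0], [4.0, 3.5, -4.0], [0.0, 3.5, 4.0]])
        res = springs_align(upper, lower, SpringSet(anchors, anchors))
        assert res.residual_spring_energy == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.transform.matrix(), np.eye(4), atol=1e-9)
        assert res.collision_free

    def test_collision_free_case_equals_closed_form(self):
        upper, lower = make_plates(gap=8.0)  # far apart, springs reachable
        rng = np.random.default_rng(4)
        anchors = np.array([[-4.0, 8.5, -4.0], [4.0, 8.5, -4.0], [0.0, 8.5, 4.0]])
        targets = anchors + rng.uniform(-1, 1, size=(3, 3))
        res = springs_align(upper, lower, SpringSet(anchors, targets))
        oracle = rigid_least_squares(anchors, targets)
        np.testing.assert_allclose(
            res.transform.apply(anchors), oracle.apply(anchors), atol=1e-6
        )

    def test_plate_contact_rests_at_surface(self):
        """Springs pulling 2 mm into the lower plate must stop at contact."""
        upper, lower = make_plates(gap=1.5)
        anchors = np.array([[-4.0, 1.5, -4.0], [4.0, 1.5, -4.0], [0.0, 1.5, 4.0]])
        targets = anchors + (0.0, -3.5, 0.0)
        tree = build_tree(lower)
        res = springs_align(upper, lower, SpringSet(anchors, targets), lower_tree=tree)
        gap = minimum_gap(upper, res.transform, tree)
        assert gap <= 1e-3
        moved = apply_transform(upper, res.transform)
        hit, _ = meshes_intersect(build_tree(moved), tree, return_pairs=False)
        assert not hit
        assert res.collision_free

    def test_deterministic(self):
        upper, lower = make_plates(gap=1.5)
        anchors = np.array([[-4.0, 1.5, -4.0], [4.0, 1.5, -4.0], [0.0, 1.5, 4.0]])
        springs = SpringSet(anchors, anchors + (0.3, -2.5, 0.1))
        r1 = springs_align(upper, lower, springs)
        r2 = springs_align(upper, lower, springs)
        np.testing.assert_array_equal(r1.transform.matrix(), r2.transform.matrix())
        assert r1.residual_spring_energy == r2.residual_spring_energy

    def test_recovery_from_displaced_arch(self, arch_pair, lower_tree):
        """Displace the upper arch, spring it back with true correspondences."""
        up, lo, lm, _ = arch_pair
        start = perturb_occlusion(
            up, lo, 5.0, 10.0, seed=11, pivot=lm.lower_midline, lower_tree=lower_tree
        )
        anchors = np.vstack([lm["UI"], lm["UMcusp_r"], lm["UMcusp_l"]])
        displaced = apply_transform(up, start)
        springs = SpringSet(start.apply(anchors), anchors)
        res = springs_align(displaced, lo, springs, lower_tree=lower_tree)
        recovered = res.transform.apply(start.apply(anchors))
        assert np.abs(recovered - anchors).max() < 0.1
        assert res.collision_free


class TestManualMove:
    def test_zero_delta_is_noop(self):
        upper, lower = make_plates(gap=1.0)
        state = RigidTransform.identity()
        out, clamped, f = manual_move(state, upper, lower, pivot=(0, 0, 0))
        assert out is state and not clamped and f == 1.0

    def test_move_away_applies_fully(self):
        upper, lower = make_plates(gap=1.0)
        out, clamped, f = manual_move(
            RigidTransform.identity(), upper, lower, pivot=(0, 0, 0),
            translation=(0, 2.0, 0),
        )
        assert not clamped and f == 1.0
        assert out.offset[1] == pytest.approx(2.0)

    def test_move_into_plate_clamps_to_contact(self):
        upper, lower = make_plates(gap=0.8)
        tree = build_tree(lower)
        out, clamped, f = manual_move(
            RigidTransform.identity(), upper, lower, pivot=(0, 0, 0),
            translation=(0, -2.0, 0), lower_tree=tree,
        )
        assert clamped
        assert f == pytest.approx(0.4, abs=1e-3)
        assert minimum_gap(upper, out, tree) <= 1e-3

    def test_clamped_rotation_keeps_feasibility(self):
        upper, lower = make_plates(gap=0.3)
        tree = build_tree(lower)
        out, clamped, f = manual_move(
            RigidTransform.identity(), upper, lower, pivot=(5.0, 0.0, 0.0),
            roll=20.0, lower_tree=tree,
        )
        assert clamped and 0 < f < 1
        moved = apply_transform(upper, out)
        hit, _ = meshes_intersect(build_tree(moved), tree, return_pairs=False)
        assert not hit


class TestSnapToContact:
    def test_snap_travels_the_gap(self):
        upper, lower = make_plates(gap=3.0)
        tree = build_tree(lower)
        T = snap_to_contact(upper, lower, (0, -1, 0), max_travel=5.0, lower_tree=tree)
        assert -T.offset[1] == pytest.approx(3.0, abs=1e-3)
        assert minimum_gap(upper, T, tree) <= 1e-3

    def test_max_travel_clamps(self):
        upper, lower = make_plates(gap=3.0)
        T = snap_to_contact(upper, lower, (0, -1, 0), max_travel=1.0)
        assert -T.offset[1] == pytest.approx(1.0)

    def test_direction_away_travels_fully(self):
        upper, lower = make_plates(gap=1.0)
        T = snap_to_contact(upper, lower, (0, 1, 0), max_travel=4.0)
        assert T.offset[1] == pytest.approx(4.0)

    def test_already_colliding_raises(self):
        upper, lower = make_plates(gap=-0.2)
        with pytest.raises(InfeasiblePoseError):
            snap_to_contact(upper, lower, (0, -1, 0), max_travel=1.0)
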