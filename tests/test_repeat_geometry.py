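"""Frames, relative transforms, quaternion averaging, screw decomposition."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pseudocycle.structure_io import BackboneResidue, RepeatSpec
from pseudocycle.repeat_geometry import (
    Frame, GeometryError, RigidTransform, average_transforms,
    average_transforms_eigen, relative_transform, repeat_screw,
    residue_frame, screw_compose, screw_decompose)
from pseudocycle.synthetic_backbones import CyclicBackboneSpec, build_cyclic
from conftest import rigid_move


def _random_transform(rng) -> RigidTransform:
    R = Rotation.random(random_state=rng).as_matrix()
    return RigidTransform.from_matrix(R, rng.normal(0, 10, 3))


class TestResidueFrame:
    def test_hand_evaluated_construction(self):
        # x along CA->C; z along (C-CA) x (N-CA) which here points +z
        res = BackboneResidue(1, "A", n_xyz=[-0.5, 1.2, 0.0],
                              ca_xyz=[0.0, 0.0, 0.0], c_xyz=[1.52, 0.0, 0.0])
        f = residue_frame(res)
        np.testing.assert_allclose(f.origin, [0, 0, 0])
        np.testing.assert_allclose(f.basis[:, 0], [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f.basis[:, 2], [0, 0, 1], atol=1e-12)

    def test_equivariance_under_rigid_rotation(self):
        rng = np.random.default_rng(0)
        res = BackboneResidue(1, "A", [-0.5, 1.2, 0.3], [0, 0, 0],
                              [1.4, 0.2, -0.4])
        R = Rotation.random(random_state=1).as_matrix()
        rot = BackboneResidue(1, "A", R @ res.n_xyz, R @ res.ca_xyz,
                              R @ res.c_xyz)
        f0, f1 = residue_frame(res), residue_frame(rot)
        np.testing.assert_allclose(f1.basis, R @ f0.basis, atol=1e-12)

    def test_collinear_atoms_raise(self):
        res = BackboneResidue(1, "A", n_xyz=[-1.2, 0, 0],
                              ca_xyz=[0, 0, 0], c_xyz=[1.5, 0, 0])
        with pytest.raises(GeometryError):
            residue_frame(res)


class TestRelativeTransform:
    def test_identity_for_equal_frames(self):
        f = Frame([1, 2, 3], np.eye(3))
        m = relative_transform(f, f)
        np.testing.assert_allclose(m.quat, [1, 0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(m.trans, 0, atol=1e-12)

    def test_72_degree_rotation_compose_and_check(self):
        R = Rotation.from_euler("z", 72, degrees=True).as_matrix()
        src = Frame([3.0, 1.0, 2.0], np.eye(3))
        dst = Frame(R @ src.origin, R @ src.basis)
        m = relative_transform(src, dst)
        np.testing.assert_allclose(m.rotation_matrix, R, atol=1e-12)
        # applying the transform to src reproduces dst exactly
        np.testing.assert_allclose(m.apply(src.origin), dst.origin, atol=1e-12)
        np.testing.assert_allclose(
            m.rotation_matrix @ src.basis, dst.basis, atol=1e-12)

    def test_inverse_composition_is_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            src = Frame(rng.normal(0, 5, 3),
                        Rotation.random(random_state=rng).as_matrix())
            dst = Frame(rng.normal(0, 5, 3),
                        Rotation.random(random_state=rng).as_matrix())
            m = relative_transform(src, dst).compose(
                relative_transform(dst, src))
            np.testing.assert_allclose(m.quat, [1, 0, 0, 0], atol=1e-9)
            np.testing.assert_allclose(m.trans, 0, atol=1e-9)


class TestAverageTransforms:
    def test_idempotent_on_duplicates(self):
        rng = np.random.default_rng(3)
        m = _random_transform(rng)
        avg = average_transforms([m, m])
        np.testing.assert_allclose(avg.quat, m.quat, atol=1e-12)
        np.testing.assert_allclose(avg.trans, m.trans, atol=1e-12)

    def test_sign_alignment_of_antipodal_quaternions(self):
        rng = np.random.default_rng(4)
        m = _random_transform(rng)
        flipped = RigidTransform.__new__(RigidTransform)
        flipped.quat = -m.quat
        flipped.trans = m.trans.copy()
        avg = average_transforms([m, flipped])
        np.testing.assert_allclose(np.abs(avg.quat @ m.quat), 1.0, atol=1e-12)

    def test_perturbed_cloud_matches_eigen_oracle(self):
        rng = np.random.default_rng(5)
        base = Rotation.random(random_state=6)
        ts = []
        for _ in range(100):
            ax = rng.normal(size=3)
            ax /= np.linalg.norm(ax)
            pert = Rotation.from_rotvec(math.radians(rng.uniform(0, 5)) * ax)
            ts.append(RigidTransform.from_matrix(
                (pert * base).as_matrix(), rng.normal(0, 1, 3)))
        avg = average_transforms(ts)
        # within 1 degree of the base rotation
        q_base = RigidTransform.from_matrix(base.as_matrix(), np.zeros(3)).quat
        ang = 2 * math.degrees(math.acos(min(1.0, abs(avg.quat @ q_base))))
        assert ang < 1.0
        # within 0.2 degrees of the eigen-decomposition average
        eig = average_transforms_eigen(ts)
        ang2 = 2 * math.degrees(math.acos(min(1.0, abs(avg.quat @ eig.quat))))
        assert ang2 < 0.2

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            average_transforms([])


class TestScrewDecompose:
    def test_pure_rotation_about_offset_axis(self):
        m = screw_compose([0, 0, 1], 72.0, 0.0, axis_point=[10, 0, 0])
        sp = screw_decompose(m)
        assert math.isclose(sp.angle_deg, 72.0, abs_tol=1e-9)
        assert sp.rise_A < 1e-9
        np.testing.assert_allclose(np.abs(sp.axis), [0, 0, 1], atol=1e-9)
        # the recovered axis point lies on the true axis (x=10, y=0)
        np.testing.assert_allclose(sp.axis_point[:2], [10, 0], atol=1e-6)

    def test_rotation_with_axial_translation(self):
        m = screw_compose([0, 0, 1], 60.0, 1.5)
        sp = screw_decompose(m)
        assert math.isclose(sp.angle_deg, 60.0, abs_tol=1e-9)
        assert math.isclose(sp.rise_A, 1.5, abs_tol=1e-9)

    def test_identity_is_degenerate_with_zero_rise(self):
        sp = screw_decompose(RigidTransform([1, 0, 0, 0], [0, 0, 0]))
        assert sp.degenerate
        assert sp.rise_A == 0.0

    def test_roundtrip_over_random_transforms(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            ax = rng.normal(size=3)
            ax /= np.linalg.norm(ax)
            ang = rng.uniform(2.0, 178.0)
            rise = rng.uniform(0.0, 5.0)
            sp = screw_decompose(
                screw_compose(ax, ang, rise, rng.normal(0, 10, 3)))
            assert abs(sp.angle_deg - ang) < 1e-6
            assert abs(sp.rise_A - rise) < 1e-6

    def test_conjugation_invariance_of_screw_invariants(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            ax = rng.normal(size=3)
            ax /= np.linalg.norm(ax)
            m = screw_compose(ax, rng.uniform(5, 175), rng.uniform(0, 4),
                              rng.normal(0, 5, 3))
            g = _random_transform(rng)
            conj = g.compose(m).compose(g.inverse())
            a, b = screw_decompose(m), screw_decompose(conj)
            assert abs(a.angle_deg - b.angle_deg) < 1e-6
            assert abs(a.rise_A - b.rise_A) < 1e-6


class TestRepeatScrew:
    def test_perfect_c5_recovers_ideal_parameters(self, c5_backbone):
        screw, deltas = repeat_screw(c5_backbone, RepeatSpec(5, 20))
        assert abs(screw.angle_deg - 72.0) < 0.5
        assert deltas.delta_rise_A < 0.05
        assert deltas.delta_rotation_deg < 0.5

    def test_cumulative_axial_offset_appears_as_rise(self):
        s, _ = build_cyclic(CyclicBackboneSpec(5, "H" * 20, inject_rise=2.0))
        _, deltas = repeat_screw(s, RepeatSpec(5, 20))
        assert abs(deltas.delta_rise_A - 2.0) < 0.1

    def test_invariance_under_global_rigid_motion(self, c5_backbone):
        spec = RepeatSpec(5, 20)
        _, d0 = repeat_screw(c5_backbone, spec)
        _, d1 = repeat_screw(rigid_move(c5_backbone, seed=11), spec)
        assert abs(d0.delta_rise_A - d1.delta_rise_A) < 1e-6
        assert abs(d0.delta_rotation_deg - d1.delta_rotation_deg) < 1e-6

    def test_n2_180_degree_rotation_handled(self):
        s, _ = build_cyclic(CyclicBackboneSpec(2, "H" * 20))
        screw, deltas = repeat_screw(s, RepeatSpec(2, 20))
        assert abs(screw.angle_deg - 180.0) < 0.5
        assert deltas.delta_rotation_deg < 0.5
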