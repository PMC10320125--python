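"""Quaternion pose algebra, pose metric, and ANM mode basis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import glowdock as gd
from glowdock.pose import (
    canonicalize_quaternion,
    compute_anm_basis,
    pose_distance,
    random_rotation_quaternion,
    rotate_point,
)
from glowdock.structures import Atom, Molecule, MoleculeKind


def _quat(rng):
    return random_rotation_quaternion(rng)


class TestRotatePoint:
    def test_identity(self):
        assert np.allclose(rotate_point([1, 0, 0, 0], [1, 2, 3]), [1, 2, 3])

    def test_half_turn_about_z(self):
        q = canonicalize_quaternion([0, 0, 0, 1])
        assert np.allclose(rotate_point(q, [1, 0, 0]), [-1, 0, 0], atol=1e-12)

    def test_isometry_on_random_point_sets(self, rng):
        pts = rng.normal(size=(20, 3))
        q = _quat(rng)
        rotated = rotate_point(q, pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(rotated[:, None] - rotated[None, :], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError, match="non-unit quaternion"):
            rotate_point([2.0, 0, 0, 0], [1, 0, 0])


class TestRandomPose:
    def test_translations_within_ball(self, rng):
        center = np.array([5.0, -3.0, 2.0])
        for _ in range(2000):
            p = gd.random_pose(center, 10.0, 0, rng)
            assert np.linalg.norm(p.translation - center) <= 10.0 + 1e-12

    def test_deterministic_per_state(self):
        a = gd.random_pose([0, 0, 0], 5.0, 3, np.random.default_rng(99))
        b = gd.random_pose([0, 0, 0], 5.0, 3, np.random.default_rng(99))
        assert np.array_equal(a.translation, b.translation)
        assert np.array_equal(a.rotation, b.rotation)
        assert np.array_equal(a.mode_amplitudes, b.mode_amplitudes)

    def test_rotation_uniformity_monte_carlo(self):
        # mean dot of uniform quaternions with a fixed one vanishes
        rng = np.random.default_rng(0)
        fixed = random_rotation_quaternion(np.random.default_rng(5))
        dots = []
        for _ in range(10_000):
            q = random_rotation_quaternion(rng)
            sign = rng.choice([-1.0, 1.0])  # undo canonicalization for the oracle
            dots.append(float(sign * q @ fixed))
        assert abs(np.mean(dots)) < 0.05

    def test_negative_mode_count_rejected(self, rng):
        with pytest.raises(ValueError, match="invalid mode count"):
            gd.random_pose([0, 0, 0], 1.0, -1, rng)


class TestApplyPose:
    def test_identity_pose_returns_input(self, toy_complex):
        _, ligand, _, _ = toy_complex
        pose = gd.Pose(ligand.centroid())
        assert np.allclose(gd.apply_pose(ligand, pose), ligand.coordinates(), atol=1e-9)

    def test_translation_shifts_centroid(self, toy_complex):
        _, ligand, _, _ = toy_complex
        pose = gd.Pose(ligand.centroid() + np.array([3.0, 4.0, 0.0]))
        coords = gd.apply_pose(ligand, pose)
        shift = coords.mean(axis=0) - ligand.coordinates().mean(axis=0)
        assert np.isclose(np.linalg.norm(shift), 5.0, atol=1e-9)

    def test_inverse_transform_recovers_input(self, toy_complex, rng):
        _, ligand, _, _ = toy_complex
        q = _quat(rng)
        pose = gd.Pose(rng.normal(size=3) * 5, q)
        coords = gd.apply_pose(ligand, pose)
        # undo: rotate back about the new centroid, translate to original
        back = rotate_point(canonicalize_quaternion([q[0], -q[1], -q[2], -q[3]]),
                            coords - pose.translation) + ligand.centroid()
        assert np.allclose(back, ligand.coordinates(), atol=1e-6)

    def test_zero_amplitudes_equal_no_basis(self, toy_complex):
        _, ligand, _, _ = toy_complex
        basis = compute_anm_basis(ligand, M=3, cutoff=8.0)
        pose = gd.Pose(ligand.centroid(), mode_amplitudes=np.zeros(3))
        assert np.allclose(gd.apply_pose(ligand, pose, basis),
                           gd.apply_pose(ligand, gd.Pose(ligand.centroid())))

    def test_mode_count_mismatch_rejected(self, toy_complex):
        _, ligand, _, _ = toy_complex
        basis = compute_anm_basis(ligand, M=3, cutoff=8.0)
        pose = gd.Pose(ligand.centroid(), mode_amplitudes=np.ones(5))
        with pytest.raises(ValueError, match="mode basis incompatible"):
            gd.apply_pose(ligand, pose, basis)


class TestPoseDistance:
    def test_zero_on_equal_poses(self, rng):
        p = gd.random_pose([0, 0, 0], 5.0, 2, rng)
        assert pose_distance(p, p) == 0.0

    def test_antipodal_quaternions_identified(self):
        q = canonicalize_quaternion([0.3, 0.5, -0.2, 0.4])
        a = gd.Pose([0, 0, 0], q)
        b = gd.Pose([0, 0, 0], -q)  # canonicalized back to q
        assert pose_distance(a, b) == 0.0

    def test_euclidean_on_translations(self):
        a = gd.Pose([0, 0, 0])
        b = gd.Pose([3, 4, 0])
        assert np.isclose(pose_distance(a, b), 5.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (gd.random_pose([0, 0, 0], 5.0, 2, rng) for _ in range(3))
        assert np.isclose(pose_distance(a, b), pose_distance(b, a))
        assert pose_distance(a, c) <= pose_distance(a, b) + pose_distance(b, c) + 1e-9


def _chain_molecule(coords, kind=None):
    atoms = [
        Atom(i + 1, "CA", "C", "ALA", i + 1, "", "A", np.asarray(c, dtype=float))
        for i, c in enumerate(coords)
    ]
    return Molecule(atoms, kind=kind)


def _dense_anm_eigenvalues(coords, cutoff):
    """Brute-force oracle: dense Hessian assembled pair by pair, numpy eigh."""
    n = len(coords)
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = coords[j] - coords[i]
            r2 = d @ d
            if np.sqrt(r2) > cutoff:
                continue
            block = -np.outer(d, d) / r2
            hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
    return np.linalg.eigvalsh(hess)


class TestAnmBasis:
    def test_six_rigid_modes_for_connected_network(self, rng):
        coords = rng.normal(size=(20, 3)) * 4.0
        mol = _chain_molecule(coords)
        basis = compute_anm_basis(mol, M=5, cutoff=15.0)
        from glowdock.pose import _anm_hessian
        eigenvalues = np.linalg.eigvalsh(_anm_hessian(coords, 15.0))
        assert np.sum(np.abs(eigenvalues) < 1e-8) == 6
        assert basis.n_modes == 5

    def test_modes_pairwise_orthonormal(self, toy_complex):
        _, ligand, _, _ = toy_complex
        basis = compute_anm_basis(ligand, M=4, cutoff=8.0)
        flat = basis.modes.reshape(4, -1)
        assert np.allclose(flat @ flat.T, np.eye(4), atol=1e-8)

    def test_collinear_chain_eigenvalues_match_dense_oracle(self):
        coords = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        from glowdock.pose import _anm_hessian
        ours = np.linalg.eigvalsh(_anm_hessian(coords, 15.0))
        oracle = _dense_anm_eigenvalues(coords, 15.0)
        assert np.allclose(np.sort(ours), np.sort(oracle), atol=1e-6)

    def test_disconnected_network_rejected(self):
        coords = np.vstack([np.random.default_rng(0).normal(size=(5, 3)),
                            np.random.default_rng(1).normal(size=(5, 3)) + 100.0])
        with pytest.raises(ValueError, match="disconnected elastic network"):
            compute_anm_basis(_chain_molecule(coords), M=2, cutoff=15.0)

    def test_membrane_receptor_refused(self, rng):
        coords = rng.normal(size=(10, 3)) * 3
        mol = _chain_molecule(coords, kind=MoleculeKind.MEMBRANE_PROTEIN)
        with pytest.raises(ValueError, match="flexibility disabled for membrane receptors"):
            compute_anm_basis(mol, M=2)
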