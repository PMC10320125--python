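"""Swarm generation, restraint/membrane filtering, glowworm initialization."""

import numpy as np
import pytest

import glowdock as gd
from glowdock.modes import MembraneModel
from glowdock.pose import random_rotation_quaternion, rotate_point
from glowdock.sampling import Swarm, generate_swarms, init_glowworms
from glowdock.structures import Atom, Molecule, MoleculeKind, RestraintSet


def _sphere_shell(n=40, radius=20.0):
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    pts = radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    atoms = [
        Atom(i + 1, "CA", "C", "ALA", i + 1, "", "A", p) for i, p in enumerate(pts)
    ]
    return Molecule(atoms, kind=MoleculeKind.PROTEIN)


class TestGenerateSwarms:
    def test_sphere_shell_centers_at_expected_radius(self):
        receptor = _sphere_shell(radius=20.0)
        swarms = generate_swarms(receptor, placement_distance=10.0)
        for s in swarms:
            assert np.isclose(np.linalg.norm(s.center), 30.0, atol=1.0)

    def test_larger_surface_yields_more_swarms(self):
        small = _sphere_shell(n=40, radius=14.0)
        large = _sphere_shell(n=160, radius=28.0)
        assert len(generate_swarms(large)) > len(generate_swarms(small))

    def test_deterministic(self):
        receptor = _sphere_shell()
        a = generate_swarms(receptor, seed=3)
        b = generate_swarms(receptor, seed=3)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.center, sb.center)

    def test_rotation_equivariance(self, rng):
        receptor = _sphere_shell()
        q = random_rotation_quaternion(rng)
        rotated = Molecule(
            [Atom(a.serial, a.name, a.element, a.residue_name, a.residue_number,
                  a.insertion_code, a.chain_id, rotate_point(q, a.coordinates))
             for a in receptor.atoms], kind=receptor.kind)
        s0 = generate_swarms(receptor)
        s1 = generate_swarms(rotated)
        assert len(s0) == len(s1)
        co_rotated = np.array([rotate_point(q, s.center) for s in s0])
        assert np.allclose(co_rotated, np.array([s.center for s in s1]), atol=1e-6)

    def test_count_override_subsamples(self):
        receptor = _sphere_shell(n=160, radius=28.0)
        swarms = generate_swarms(receptor, n_swarms=5)
        assert len(swarms) == 5

    def test_tiny_receptor_rejected(self):
        atoms = [Atom(1, "CA", "C", "ALA", 1, "", "A", np.zeros(3))]
        with pytest.raises(ValueError, match="receptor too small"):
            generate_swarms(Molecule(atoms, kind=MoleculeKind.PROTEIN))


class TestRestraintFilter:
    def test_kept_centers_near_restraint(self):
        receptor = _sphere_shell()
        swarms = generate_swarms(receptor)
        north = max(receptor.atoms, key=lambda a: a.coordinates[2])
        restraints = RestraintSet(receptor=[north.residue_ref])
        kept = gd.filter_swarms_by_restraints(swarms, receptor, restraints, keep_cutoff=20.0)
        assert 0 < len(kept) < len(swarms)
        for s in kept:
            assert np.linalg.norm(s.center - north.coordinates) <= 20.0

    def test_no_restraints_is_identity(self):
        receptor = _sphere_shell()
        swarms = generate_swarms(receptor)
        assert gd.filter_swarms_by_restraints(swarms, receptor, None) == swarms

    def test_survivors_are_a_pure_subset(self):
        receptor = _sphere_shell()
        swarms = generate_swarms(receptor)
        north = max(receptor.atoms, key=lambda a: a.coordinates[2])
        kept = gd.filter_swarms_by_restraints(
            swarms, receptor, RestraintSet(receptor=[north.residue_ref]))
        originals = {s.id: s for s in swarms}
        assert all(originals[s.id] is s for s in kept)

    def test_unknown_restraint_residue(self):
        receptor = _sphere_shell()
        swarms = generate_swarms(receptor)
        with pytest.raises(KeyError, match="unknown restraint residue Z.999"):
            gd.filter_swarms_by_restraints(
                swarms, receptor, RestraintSet(receptor=[gd.ResidueRef("Z", 999)]))


class TestMembraneFilter:
    @pytest.fixture()
    def slab(self):
        beads = np.array([[x, y, z] for x in (-10, 10) for y in (-10, 10) for z in (-15, 15)])
        return MembraneModel(beads=beads, z_min=-15.0, z_max=15.0)

    @pytest.mark.parametrize("z, kept", [(30.0, True), (0.0, False), (19.0, False), (-25.0, True)])
    def test_slab_plus_cushion_boundary(self, slab, z, kept):
        swarms = [Swarm(0, np.array([0.0, 0.0, z]), 10.0),
                  Swarm(1, np.array([0.0, 0.0, 40.0]), 10.0)]
        result = gd.filter_swarms_by_membrane(swarms, slab, cushion=5.0)
        assert (0 in [s.id for s in result]) is kept

    def test_all_inside_slab_is_an_error(self, slab):
        swarms = [Swarm(0, np.zeros(3), 10.0)]
        with pytest.raises(ValueError, match="membrane eliminates all swarms"):
            gd.filter_swarms_by_membrane(swarms, slab)

    def test_commutes_with_restraint_filter(self, slab):
        receptor = _sphere_shell()
        swarms = generate_swarms(receptor)
        north = max(receptor.atoms, key=lambda a: a.coordinates[2])
        restraints = RestraintSet(receptor=[north.residue_ref])
        ab = gd.filter_swarms_by_membrane(
            gd.filter_swarms_by_restraints(swarms, receptor, restraints), slab)
        ba = gd.filter_swarms_by_restraints(
            gd.filter_swarms_by_membrane(swarms, slab), receptor, restraints)
        assert [s.id for s in ab] == [s.id for s in ba]


class TestInitGlowworms:
    def test_population_size_luciferin_and_determinism(self, toy_complex):
        _, ligand, _, _ = toy_complex
        swarm_a = Swarm(0, np.array([0.0, 0, 30.0]), 10.0)
        swarm_b = Swarm(0, np.array([0.0, 0, 30.0]), 10.0)
        init_glowworms(swarm_a, ligand, n_glowworms=25, rng=np.random.default_rng(3))
        init_glowworms(swarm_b, ligand, n_glowworms=25, rng=np.random.default_rng(3))
        assert len(swarm_a.glowworms) == 25
        assert all(w.luciferin == 5.0 for w in swarm_a.glowworms)
        for wa, wb in zip(swarm_a.glowworms, swarm_b.glowworms):
            assert np.array_equal(wa.pose.rotation, wb.pose.rotation)

    def test_unrestrained_orientations_are_uniform(self, toy_complex):
        _, ligand, _, _ = toy_complex
        swarm = Swarm(0, np.array([0.0, 0, 30.0]), 10.0)
        init_glowworms(swarm, ligand, n_glowworms=1000, rng=np.random.default_rng(11))
        quats = np.array([w.pose.rotation for w in swarm.glowworms])
        signs = np.random.default_rng(0).choice([-1.0, 1.0], size=len(quats))
        mean_dot = np.mean((signs[:, None] * quats) @ quats[0])
        assert abs(mean_dot) < 0.1

    def test_restraint_pair_orientation_faces_patch(self, toy_complex):
        receptor, ligand, native, restraints = toy_complex
        one_pair = RestraintSet(receptor=[restraints.receptor[0]], ligand=[restraints.ligand[0]])
        swarm = Swarm(0, native.translation + np.array([0.0, 0, 8.0]), 10.0)
        init_glowworms(swarm, ligand, n_glowworms=50, restraints=one_pair,
                       receptor=receptor, rng=np.random.default_rng(5),
                       max_perturbation_deg=0.0)
        r_centroid = np.mean([receptor.atoms[i].coordinates
                              for i in receptor.residue_atom_indices(one_pair.receptor[0])], axis=0)
        l_indices = ligand.residue_atom_indices(one_pair.ligand[0])
        for w in swarm.glowworms:
            coords = gd.apply_pose(ligand, w.pose)
            to_patch = r_centroid - w.pose.translation
            to_patch /= np.linalg.norm(to_patch)
            l_dir = coords[l_indices].mean(axis=0) - w.pose.translation
            l_dir /= np.linalg.norm(l_dir)
            assert l_dir @ to_patch > 0.999

    def test_unknown_ligand_restraint_rejected(self, toy_complex):
        receptor, ligand, native, restraints = toy_complex
        bad = RestraintSet(receptor=[restraints.receptor[0]], ligand=[gd.ResidueRef("B", 99)])
        swarm = Swarm(0, native.translation, 10.0)
        with pytest.raises(KeyError, match="unknown restraint residue"):
            init_glowworms(swarm, ligand, n_glowworms=5, restraints=bad,
                           receptor=receptor, rng=np.random.default_rng(0))
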