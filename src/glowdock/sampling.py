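"""Swarm generation over the receptor surface and glowworm initialization.

Swarms are sampling loci anchored just off the receptor surface: every
solvent-accessible heavy atom proposes a candidate center displaced outward
(away from the receptor centroid) by the placement distance, and candidates
are greedily thinned so no two centers are closer than the density spacing.
The swarm count is therefore a function of receptor size and shape rather
than a fixed number.

Restraint and membrane filters are pure subset predicates on swarm centers:
restraints keep swarms near declared interface residues; an explicit
coarse-grained membrane removes every swarm inside the slab spanned by the
bead z-extrema plus a cushion, restricting sampling to extramembranous
space.

When ligand-side restraints exist, initial ligand orientations are not
uniform: each agent draws one receptor/ligand restraint pair and is rotated
so the ligand restraint residue faces the receptor patch, then jittered by a
small random rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .gso import Glowworm, GSOParameters
from .pose import Pose, canonicalize_quaternion, quaternion_multiply, random_pose
from .structures import Molecule, RestraintSet

__all__ = [
    "Swarm",
    "solvent_accessible_mask",
    "generate_swarms",
    "filter_swarms_by_restraints",
    "filter_swarms_by_membrane",
    "init_glowworms",
]

PROBE_RADIUS = 1.4  # Å, water rolling probe
_N_SPHERE_POINTS = 92


@dataclass
class Swarm:
    """A sampling locus on the receptor surface with its glowworm population."""

    id: int
    center: np.ndarray
    radius: float
    glowworms: list[Glowworm] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("swarm radius must be positive")


def _unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def solvent_accessible_mask(molecule: Molecule, probe: float = PROBE_RADIUS) -> np.ndarray:
    """Heavy atoms with nonzero solvent accessibility (Shrake–Rupley test points).

    Returns a boolean mask over all atoms; hydrogens are always False. An
    atom is accessible if any probe-inflated sphere point survives occlusion
    by every neighboring atom sphere.
    """
    heavy = molecule.heavy_mask
    coords = molecule.coordinates()[heavy]
    radii = np.array([a.radius for a in molecule.atoms])[heavy] + probe
    tree = cKDTree(coords)
    sphere = _unit_sphere_points(_N_SPHERE_POINTS)
    max_reach = 2.0 * radii.max()
    accessible = np.zeros(len(coords), dtype=bool)
    for i, (center, radius) in enumerate(zip(coords, radii)):
        points = center + radius * sphere
        free = np.ones(len(points), dtype=bool)
        for j in tree.query_ball_point(center, max_reach):
            if j == i:
                continue
            free &= np.linalg.norm(points - coords[j], axis=1) >= radii[j]
            if not free.any():
                break
        accessible[i] = free.any()
    mask = np.zeros(len(molecule), dtype=bool)
    mask[np.flatnonzero(heavy)] = accessible
    return mask


def generate_swarms(
    receptor: Molecule,
    placement_distance: float = 10.0,
    swarm_radius: float = 10.0,
    density_spacing: float = 10.0,
    seed: int | None = None,
    n_swarms: int | None = None,
) -> list[Swarm]:
    """Place swarm centers over the receptor surface.

    Each surface heavy atom proposes a center at ``placement_distance`` along
    its outward radial direction; candidates are visited by descending
    distance from the receptor centroid (ties by atom serial) and greedily
    accepted when at least ``density_spacing`` from every accepted center.
    ``n_swarms`` overrides the dynamic count: subsampling evenly when fewer
    are requested, shrinking the spacing when more are.
    """
    if len(receptor) < 4:
        raise ValueError("receptor too small")
    centroid = receptor.centroid()
    surface = solvent_accessible_mask(receptor)
    coords = receptor.coordinates()
    serials = np.array([a.serial for a in receptor.atoms])
    idx = np.flatnonzero(surface)
    radial = coords[idx] - centroid
    norms = np.linalg.norm(radial, axis=1)
    usable = norms > 1e-9
    idx, radial, norms = idx[usable], radial[usable], norms[usable]
    candidates = coords[idx] + placement_distance * radial / norms[:, None]
    order = np.lexsort((serials[idx], -norms))

    def _thin(spacing: float) -> np.ndarray:
        accepted: list[int] = []
        for i in order:
            point = candidates[i]
            if all(np.linalg.norm(point - candidates[j]) >= spacing for j in accepted):
                accepted.append(i)
        return np.array(accepted, dtype=int)

    accepted = _thin(density_spacing)
    if n_swarms is not None and n_swarms > len(accepted):
        spacing = density_spacing
        while len(accepted) < n_swarms and spacing > 0.1:
            spacing *= 0.9
            accepted = _thin(spacing)
    if n_swarms is not None and n_swarms < len(accepted):
        keep = np.linspace(0, len(accepted) - 1, n_swarms).round().astype(int)
        accepted = accepted[keep]
    return [
        Swarm(id=k, center=candidates[i], radius=swarm_radius)
        for k, i in enumerate(accepted)
    ]


def _restraint_heavy_coords(molecule: Molecule, refs) -> np.ndarray:
    coords = []
    for ref in refs:
        indices = molecule.residue_atom_indices(ref)
        coords.extend(
            molecule.atoms[i].coordinates for i in indices if not molecule.atoms[i].is_hydrogen
        )
    return np.array(coords)


def filter_swarms_by_restraints(
    swarms: list[Swarm],
    receptor: Molecule,
    restraints: RestraintSet | None,
    keep_cutoff: float = 20.0,
) -> list[Swarm]:
    """Keep swarms whose center lies within ``keep_cutoff`` of a restraint residue.

    A no-op without receptor restraints; errors if the filter empties the
    swarm list (the declared interface is unreachable by any swarm).
    """
    if restraints is None or not restraints.receptor:
        return list(swarms)
    anchor = _restraint_heavy_coords(receptor, restraints.receptor)
    tree = cKDTree(anchor)
    kept = [s for s in swarms if tree.query(s.center, k=1)[0] <= keep_cutoff]
    if not kept:
        raise ValueError("restraints eliminate all swarms")
    return kept


def filter_swarms_by_membrane(swarms: list[Swarm], membrane, cushion: float = 5.0) -> list[Swarm]:
    """Drop swarms inside the membrane slab (bead z-extrema plus cushion)."""
    z_low = membrane.z_min - cushion
    z_high = membrane.z_max + cushion
    kept = [s for s in swarms if s.center[2] > z_high or s.center[2] < z_low]
    if not kept:
        raise ValueError("membrane eliminates all swarms")
    return kept


def _alignment_quaternion(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector v_from onto unit vector v_to."""
    v_from = v_from / np.linalg.norm(v_from)
    v_to = v_to / np.linalg.norm(v_to)
    dot = float(np.clip(v_from @ v_to, -1.0, 1.0))
    axis = np.cross(v_from, v_to)
    axis_norm = np.linalg.norm(axis)
    if axis_norm < 1e-12:
        if dot > 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        # antiparallel: rotate pi about any axis perpendicular to v_from
        perp = np.cross(v_from, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(v_from, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return canonicalize_quaternion(np.array([0.0, *perp]))
    angle = np.arctan2(axis_norm, dot)
    axis /= axis_norm
    return canonicalize_quaternion(
        np.array([np.cos(angle / 2.0), *(np.sin(angle / 2.0) * axis)])
    )


def _axis_angle_quaternion(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return np.array([np.cos(angle / 2.0), *(np.sin(angle / 2.0) * axis)])


def init_glowworms(
    swarm: Swarm,
    ligand: Molecule,
    n_glowworms: int = 200,
    restraints: RestraintSet | None = None,
    receptor: Molecule | None = None,
    M: int = 0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    params: GSOParameters | None = None,
    max_perturbation_deg: float = 15.0,
) -> Swarm:
    """Populate a swarm with ``n_glowworms`` random-pose agents.

    With ligand-side restraints, each agent draws a (receptor restraint,
    ligand restraint) residue pair uniformly and its rotation is the minimal
    one aligning the ligand-centroid→ligand-restraint direction onto the
    ligand-centroid→receptor-restraint direction, composed with a random
    perturbation of at most ``max_perturbation_deg``.
    """
    if n_glowworms < 2:
        raise ValueError("need at least 2 glowworms per swarm")
    params = params or GSOParameters()
    rng = np.random.default_rng(seed) if rng is None else rng
    oriented = restraints is not None and bool(restraints.ligand)
    if oriented:
        if receptor is None:
            raise ValueError("receptor required for restraint-oriented initialization")
        rec_patch_centroids = [
            _restraint_heavy_coords(receptor, [ref]).mean(axis=0) for ref in restraints.receptor
        ]
        lig_centroid = ligand.centroid()
        lig_directions = []
        for ref in restraints.ligand:
            res_centroid = _restraint_heavy_coords(ligand, [ref]).mean(axis=0)
            lig_directions.append(res_centroid - lig_centroid)
    r0 = params.initial_vision if params.initial_vision is not None else params.r_s / 2.0
    agents: list[Glowworm] = []
    for i in range(n_glowworms):
        pose = random_pose(swarm.center, swarm.radius, M, rng)
        if oriented:
            r_centroid = rec_patch_centroids[int(rng.integers(len(rec_patch_centroids)))]
            direction_l = lig_directions[int(rng.integers(len(lig_directions)))]
            direction_r = r_centroid - pose.translation
            align = _alignment_quaternion(direction_l, direction_r)
            if max_perturbation_deg > 0:
                axis = rng.normal(size=3)
                angle = np.deg2rad(max_perturbation_deg) * rng.random()
                jitter = _axis_angle_quaternion(axis, angle)
                rotation = quaternion_multiply(jitter, align)
            else:
                rotation = align
            pose = Pose(pose.translation, canonicalize_quaternion(rotation), pose.mode_amplitudes)
        agents.append(Glowworm(pose=pose, luciferin=params.ell0, vision_range=r0, id=i))
    swarm.glowworms = agents
    return swarm
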