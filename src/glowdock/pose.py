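"""Pose representation and geometry.

A ligand pose is a rigid-body placement — a translation of the ligand's
heavy-atom centroid plus a unit quaternion rotation about it — optionally
augmented by anisotropic-network-model (ANM) mode amplitudes that deform the
backbone. Quaternions are kept in canonical sign (w >= 0; if w == 0, the
first nonzero component positive) so that the antipodal pair q and -q, which
encode the same rotation, compare equal under the pose metric.

The pose metric used for glowworm neighborhoods concatenates translation
(Å), the quaternion difference scaled by ``w_q`` (default 10 Å per unit of
quaternion distance, so a large reorientation "costs" about as much as a
10 Å shift), and the mode-amplitude difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structures import Molecule, MoleculeKind

__all__ = [
    "Pose",
    "ModeBasis",
    "DEFAULT_QUATERNION_WEIGHT",
    "canonicalize_quaternion",
    "quaternion_multiply",
    "random_rotation_quaternion",
    "rotate_point",
    "random_pose",
    "apply_pose",
    "pose_distance",
    "compute_anm_basis",
]

DEFAULT_QUATERNION_WEIGHT = 10.0  # Å per unit quaternion distance in the pose metric

_IDENTITY_Q = np.array([1.0, 0.0, 0.0, 0.0])


def canonicalize_quaternion(q: np.ndarray) -> np.ndarray:
    """Normalize to unit length and fix the sign convention (w >= 0)."""
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q)
    if norm == 0.0 or not np.all(np.isfinite(q)):
        raise ValueError("non-unit quaternion: zero or non-finite")
    q = q / norm
    for component in q:
        if component > 0:
            break
        if component < 0:
            q = -q
            break
    return q


def quaternion_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b in (w, x, y, z) convention."""
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


@dataclass
class Pose:
    """Ligand placement: translation (Å), unit quaternion, mode amplitudes."""

    translation: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: _IDENTITY_Q.copy())
    mode_amplitudes: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        if self.translation.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        q = np.asarray(self.rotation, dtype=float)
        if q.shape != (4,):
            raise ValueError("rotation must be a quaternion (w, x, y, z)")
        if abs(np.linalg.norm(q) - 1.0) > 1e-6:
            raise ValueError("non-unit quaternion")
        self.rotation = canonicalize_quaternion(q)
        self.mode_amplitudes = np.asarray(self.mode_amplitudes, dtype=float).ravel()

    def copy(self) -> "Pose":
        return Pose(self.translation.copy(), self.rotation.copy(), self.mode_amplitudes.copy())

    def as_vector(self, w_q: float = DEFAULT_QUATERNION_WEIGHT) -> np.ndarray:
        """Concatenated metric-space coordinates [t, w_q*q, amplitudes]."""
        return np.concatenate([self.translation, w_q * self.rotation, self.mode_amplitudes])


@dataclass
class ModeBasis:
    """Orthonormal Cα displacement modes scaled to Å by ``scale``.

    ``modes`` has shape (M, n_ca, 3); each flattened mode has unit norm and
    the modes are pairwise orthogonal.
    """

    modes: np.ndarray
    scale: float = 3.0
    eigenvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=float)
        if self.modes.ndim != 3 or self.modes.shape[2] != 3:
            raise ValueError("modes must have shape (M, n_ca, 3)")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def n_ca(self) -> int:
        return self.modes.shape[1]


def random_rotation_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform rotation on SO(3), Shoemake's subgroup-algorithm construction."""
    u1, u2, u3 = rng.random(3)
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    t2, t3 = 2.0 * np.pi * u2, 2.0 * np.pi * u3
    q = np.array([b * np.cos(t3), a * np.sin(t2), a * np.cos(t2), b * np.sin(t3)])
    return canonicalize_quaternion(q)


def random_pose(
    swarm_center: np.ndarray,
    swarm_radius: float,
    M: int = 0,
    rng: np.random.Generator | None = None,
) -> Pose:
    """Draw a pose uniformly: translation in a ball, rotation on SO(3).

    Mode amplitudes are i.i.d. standard normal. Fully reproducible for a
    fixed generator state.
    """
    if M < 0:
        raise ValueError("invalid mode count")
    if swarm_radius <= 0:
        raise ValueError("swarm radius must be positive")
    rng = np.random.default_rng() if rng is None else rng
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = swarm_radius * rng.random() ** (1.0 / 3.0)
    translation = np.asarray(swarm_center, dtype=float) + radius * direction
    rotation = random_rotation_quaternion(rng)
    amplitudes = rng.normal(size=M)
    return Pose(translation, rotation, amplitudes)


def rotate_point(q: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Rotate point(s) ``p`` by unit quaternion ``q`` (conjugation q p q*)."""
    q = np.asarray(q, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-6:
        raise ValueError("non-unit quaternion")
    w, x, y, z = q
    rot = Rotation.from_quat([x, y, z, w])  # scipy uses (x, y, z, w)
    return rot.apply(np.asarray(p, dtype=float))


def apply_pose(ligand: Molecule, pose: Pose, basis: ModeBasis | None = None) -> np.ndarray:
    """Coordinates of all ligand atoms under a pose.

    The ligand is (1) deformed by the ANM modes (each residue's atoms rigidly
    follow its Cα displacement), (2) rotated about its original heavy-atom
    centroid, and (3) translated so the centroid lands on
    ``pose.translation``.
    """
    coords = ligand.coordinates()
    centroid = ligand.centroid()
    if basis is not None and pose.mode_amplitudes.size:
        if pose.mode_amplitudes.size != basis.n_modes:
            raise ValueError("mode basis incompatible: amplitude count != mode count")
        anchors = ligand.anchor_atom_indices()
        if basis.n_ca != len(anchors):
            raise ValueError("mode basis incompatible: Cα count mismatch")
        # (n_ca, 3) displacement summed over modes
        disp = np.tensordot(pose.mode_amplitudes, basis.modes, axes=1) * basis.scale
        for res_i, indices in enumerate(ligand.residue_index.values()):
            coords[indices] += disp[res_i]
    elif pose.mode_amplitudes.size and basis is None and np.any(pose.mode_amplitudes != 0.0):
        raise ValueError("mode basis incompatible: amplitudes given without a basis")
    rotated = rotate_point(pose.rotation, coords - centroid)
    return rotated + pose.translation


def pose_distance(a: Pose, b: Pose, w_q: float = DEFAULT_QUATERNION_WEIGHT) -> float:
    """Euclidean metric on the concatenated pose space.

    Canonical quaternion signs make this insensitive to the q/-q ambiguity.
    """
    if a.mode_amplitudes.size != b.mode_amplitudes.size:
        raise ValueError("pose amplitude lengths differ")
    return float(np.linalg.norm(a.as_vector(w_q) - b.as_vector(w_q)))


def _anm_hessian(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """3n x 3n ANM Hessian with unit springs between Cα pairs within cutoff."""
    n = len(coords)
    hessian = np.zeros((3 * n, 3 * n))
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff):
        d = coords[j] - coords[i]
        d2 = d @ d
        if d2 == 0.0:
            continue
        block = -np.outer(d, d) / d2
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hessian


def compute_anm_basis(
    molecule: Molecule,
    M: int = 10,
    cutoff: float = 15.0,
    scale: float = 3.0,
) -> ModeBasis:
    """Lowest-frequency non-rigid ANM modes over the Cα network.

    Builds the anisotropic-network-model Hessian (uniform springs, 15 Å
    cutoff by default), diagonalizes it, skips the near-zero rigid-body
    modes, and returns the next ``M`` eigenvectors orthonormalized as a
    :class:`ModeBasis`. Membrane-associated receptors refuse flexibility.
    """
    if molecule.kind is MoleculeKind.MEMBRANE_PROTEIN:
        raise ValueError("flexibility disabled for membrane receptors")
    ca = [a.coordinates for a in molecule.atoms if a.name == "CA"]
    if len(ca) < 3:
        raise ValueError("ANM requires at least 3 Cα atoms")
    coords = np.array(ca)
    n = len(coords)
    tree = cKDTree(coords)
    adjacency = tree.sparse_distance_matrix(tree, cutoff)
    n_components, _ = connected_components(adjacency.tocsr(), directed=False)
    if n_components > 1:
        raise ValueError("disconnected elastic network")
    eigenvalues, eigenvectors = eigh(_anm_hessian(coords, cutoff))
    nonrigid = np.flatnonzero(eigenvalues > 1e-8)
    if len(nonrigid) < M:
        raise ValueError(f"only {len(nonrigid)} non-rigid modes available, {M} requested")
    selected = eigenvectors[:, nonrigid[:M]].T  # (M, 3n), orthonormal from eigh
    modes = selected.reshape(M, n, 3)
    return ModeBasis(modes=modes, scale=scale, eigenvalues=eigenvalues[nonrigid[:M]])
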