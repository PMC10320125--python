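"""Pose scoring: pairwise potential, restraint satisfaction, biased objective.

The default scoring function is a soft-core 12-6 Lennard-Jones term plus a
distance-screened Coulomb term over receptor–ligand heavy-atom pairs within a
cutoff:

    E = sum_pairs eps * [(sigma_ij / r')^12 - 2 (sigma_ij / r')^6]
        + k_c * q_i * q_j / (eps_r * r'),        r' = max(r, clash_floor)

with sigma_ij = r_i + r_j (sum of per-element radii) and the raw score
S = -E, so higher is better. The 1 Å distance clamp keeps early random
sampling free of singularities; formal charges are placed on the usual
titratable side-chain atoms and DNA phosphate oxygens.

When residue restraints are declared, the fraction of restraint residues in
heavy-atom contact with the partner (f_sat) multiplicatively biases the
objective the optimizer sees, while the reported score stays the raw S.
Scoring functions are pluggable by name via :func:`register_scoring`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .structures import Molecule, RestraintSet

__all__ = [
    "ScoringParameters",
    "ScoreBreakdown",
    "assign_parameters",
    "score_pose",
    "satisfied_fraction",
    "biased_objective",
    "DockingObjective",
    "register_scoring",
    "get_scoring",
    "SCORING_FUNCTIONS",
]


@dataclass
class ScoringParameters:
    """Knobs of the default pairwise potential (kcal/mol, Å, e)."""

    vdw_epsilon: float = 0.1
    element_radii: dict[str, float] = field(
        default_factory=lambda: {"C": 1.9, "N": 1.7, "O": 1.6, "S": 2.0, "P": 2.1}
    )
    default_radius: float = 1.8
    dielectric: float = 15.0
    coulomb_constant: float = 332.0
    cutoff: float = 10.0
    clash_floor: float = 1.0
    contact_cutoff: float = 5.0  # d_c for restraint satisfaction
    bias_floor: float = 0.01  # eps_b: worst multiplicative penalty at f_sat = 0

    def __post_init__(self) -> None:
        if not (self.cutoff > self.clash_floor > 0):
            raise ValueError("require cutoff > clash_floor > 0")
        if not (0 < self.bias_floor <= 1):
            raise ValueError("bias_floor must be in (0, 1]")


# Formal charges on titratable side-chain atoms and DNA phosphate oxygens.
_FORMAL_CHARGES: dict[tuple[str, str], float] = {
    ("ASP", "OD1"): -0.5,
    ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5,
    ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5,
    ("ARG", "NH2"): 0.5,
}
_DNA_PHOSPHATE_OXYGENS = {"OP1", "OP2"}


@dataclass
class ScoreBreakdown:
    """Raw score, restraint satisfaction, and the objective fed to GSO."""

    raw: float
    f_sat: float
    objective: float


def assign_parameters(molecule: Molecule, params: ScoringParameters | None = None) -> None:
    """Fill per-atom radius and formal charge in place from the element map."""
    params = params or ScoringParameters()
    for atom in molecule.atoms:
        atom.radius = params.element_radii.get(atom.element, params.default_radius)
        if atom.residue_name.startswith("D") and atom.name in _DNA_PHOSPHATE_OXYGENS:
            atom.charge = -0.5
        else:
            atom.charge = _FORMAL_CHARGES.get((atom.residue_name, atom.name), 0.0)


def _heavy_arrays(molecule: Molecule) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mask = molecule.heavy_mask
    coords = molecule.coordinates()[mask]
    radii = np.array([a.radius for a in molecule.atoms])[mask]
    charges = np.array([a.charge for a in molecule.atoms])[mask]
    return coords, radii, charges


def _pair_energy(
    r: np.ndarray,
    sigma: np.ndarray,
    qq: np.ndarray,
    params: ScoringParameters,
) -> float:
    rp = np.maximum(r, params.clash_floor)
    ratio6 = (sigma / rp) ** 6
    lj = params.vdw_epsilon * (ratio6 * ratio6 - 2.0 * ratio6)
    coulomb = params.coulomb_constant * qq / (params.dielectric * rp)
    return float(np.sum(lj + coulomb))


def score_pose(
    receptor: Molecule,
    ligand: Molecule,
    ligand_coords: np.ndarray,
    params: ScoringParameters | None = None,
) -> float:
    """Raw score S = -E of a posed ligand against the receptor.

    Convenience wrapper over :class:`DockingObjective` for one-shot scoring;
    ``ligand_coords`` are full-molecule coordinates (hydrogens are masked
    internally). Returns 0 when no pair falls within the cutoff.
    """
    params = params or ScoringParameters()
    objective = DockingObjective(receptor, ligand, params=params)
    return objective.score_coordinates(ligand_coords)


def satisfied_fraction(
    receptor: Molecule,
    ligand: Molecule,
    ligand_coords: np.ndarray,
    restraints: RestraintSet,
    d_c: float | None = None,
) -> float:
    """Fraction of restraint residues in heavy-atom contact with the partner.

    Receptor- and ligand-side restraints are pooled; a residue counts as
    satisfied when any of its heavy atoms lies within ``d_c`` of any heavy
    atom of the other molecule.
    """
    if not restraints:
        raise ValueError("satisfied_fraction requires non-empty restraints")
    params = ScoringParameters() if d_c is None else ScoringParameters(contact_cutoff=d_c)
    objective = DockingObjective(receptor, ligand, params=params, restraints=restraints)
    return objective.satisfaction(ligand_coords)


def biased_objective(
    S: float,
    f_sat: float,
    params: ScoringParameters | None = None,
    restraints_present: bool = True,
) -> float:
    """Scale the raw score by restraint satisfaction.

    J = S * max(f_sat, eps_b) for S > 0 and J = S / max(f_sat, eps_b) for
    S <= 0, so restraint violation always worsens the objective whatever the
    sign of S. Without restraints, J = S.
    """
    if not restraints_present:
        return S
    params = params or ScoringParameters()
    if not (0.0 <= f_sat <= 1.0):
        raise ValueError("f_sat must lie in [0, 1]")
    factor = max(f_sat, params.bias_floor)
    return S * factor if S > 0 else S / factor


class DockingObjective:
    """Callable pose objective binding receptor, ligand, parameters, restraints.

    Precomputes the receptor heavy-atom KD-tree and restraint atom indices so
    per-pose evaluation is a single neighbor query. Calling it with a
    :class:`~glowdock.pose.Pose` returns a :class:`ScoreBreakdown`.
    """

    def __init__(
        self,
        receptor: Molecule,
        ligand: Molecule,
        params: ScoringParameters | None = None,
        restraints: RestraintSet | None = None,
        basis=None,
    ):
        self.receptor = receptor
        self.ligand = ligand
        self.params = params or ScoringParameters()
        self.restraints = restraints if restraints else None
        self.basis = basis
        assign_parameters(receptor, self.params)
        assign_parameters(ligand, self.params)
        self._rec_coords, self._rec_radii, self._rec_charges = _heavy_arrays(receptor)
        self._rec_tree = cKDTree(self._rec_coords)
        self._lig_heavy = ligand.heavy_mask
        self._lig_radii = np.array([a.radius for a in ligand.atoms])[self._lig_heavy]
        self._lig_charges = np.array([a.charge for a in ligand.atoms])[self._lig_heavy]
        if self.restraints is not None:
            self._rec_restraint_atoms = [
                np.array(
                    [i for i in receptor.residue_atom_indices(ref) if not receptor.atoms[i].is_hydrogen]
                )
                for ref in self.restraints.receptor
            ]
            # ligand restraint atom indices within the heavy-atom subarray
            heavy_pos = np.cumsum(self._lig_heavy) - 1
            self._lig_restraint_atoms = [
                heavy_pos[[i for i in ligand.residue_atom_indices(ref) if not ligand.atoms[i].is_hydrogen]]
                for ref in self.restraints.ligand
            ]

    # -- components -------------------------------------------------------

    def score_coordinates(self, ligand_coords: np.ndarray) -> float:
        """Raw score S for full-molecule ligand coordinates."""
        lig = np.asarray(ligand_coords, dtype=float)[self._lig_heavy]
        neighbor_lists = self._rec_tree.query_ball_point(lig, self.params.cutoff)
        li = np.fromiter(
            (i for i, lst in enumerate(neighbor_lists) for _ in lst), dtype=int
        )
        if li.size == 0:
            return 0.0
        ri = np.fromiter((j for lst in neighbor_lists for j in lst), dtype=int)
        r = np.linalg.norm(lig[li] - self._rec_coords[ri], axis=1)
        sigma = self._lig_radii[li] + self._rec_radii[ri]
        qq = self._lig_charges[li] * self._rec_charges[ri]
        return -_pair_energy(r, sigma, qq, self.params)

    def satisfaction(self, ligand_coords: np.ndarray) -> float:
        """Pooled restraint satisfaction f_sat for posed ligand coordinates."""
        if self.restraints is None:
            return 1.0
        d_c = self.params.contact_cutoff
        lig = np.asarray(ligand_coords, dtype=float)[self._lig_heavy]
        lig_tree = cKDTree(lig)
        satisfied = 0
        total = 0
        for atom_idx in self._rec_restraint_atoms:
            total += 1
            dists, _ = lig_tree.query(self._rec_coords[atom_idx], k=1)
            if np.min(dists) <= d_c:
                satisfied += 1
        for atom_idx in self._lig_restraint_atoms:
            total += 1
            dists, _ = self._rec_tree.query(lig[atom_idx], k=1)
            if np.min(dists) <= d_c:
                satisfied += 1
        return satisfied / total if total else 1.0

    # -- pose interface ---------------------------------------------------

    def __call__(self, pose) -> ScoreBreakdown:
        from .pose import apply_pose

        coords = apply_pose(self.ligand, pose, self.basis)
        raw = self.score_coordinates(coords)
        if self.restraints is None:
            return ScoreBreakdown(raw=raw, f_sat=1.0, objective=raw)
        f_sat = self.satisfaction(coords)
        return ScoreBreakdown(
            raw=raw,
            f_sat=f_sat,
            objective=biased_objective(raw, f_sat, self.params, restraints_present=True),
        )


ObjectiveFactory = Callable[..., DockingObjective]

SCORING_FUNCTIONS: dict[str, ObjectiveFactory] = {}


def register_scoring(name: str):
    """Register an objective factory under ``name`` (plug-in contract).

    A factory takes (receptor, ligand, params=..., restraints=..., basis=...)
    and returns a callable mapping a pose to a finite :class:`ScoreBreakdown`.
    """

    def decorator(factory: ObjectiveFactory) -> ObjectiveFactory:
        SCORING_FUNCTIONS[name] = factory
        return factory

    return decorator


register_scoring("default")(DockingObjective)


def get_scoring(name: str) -> ObjectiveFactory:
    try:
        return SCORING_FUNCTIONS[name]
    except KeyError:
        raise KeyError(f"unknown scoring function {name!r}; registered: {sorted(SCORING_FUNCTIONS)}") from None
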