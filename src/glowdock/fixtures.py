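"""Synthetic structure generators.

Every pipeline stage is testable and demonstrable without downloading a
single PDB file: this module builds extended peptides from sequence with
ideal backbone geometry, a toy receptor–ligand complex with a known native
pose and ground-truth interface restraints, and a synthetic Fv-like antibody
numbered for the CDR schemes. All generators are deterministic per seed.

The toy complex is a pseudo-protein shell with a binding groove molded
around a helix-like ligand: wall clusters are carved radially until they
just clear the ligand at the potential's pair-distance optimum, and an
aperiodic set of salt bridges pins the binding register, so the native pose
is a genuine score optimum of the default potential by construction.
Interface residues within 5 Å across the native interface become the
ground-truth restraints.
"""

from __future__ import annotations

import numpy as np

from .pose import Pose
from .structures import Atom, Molecule, MoleculeKind, RestraintSet

__all__ = [
    "build_extended_peptide",
    "make_toy_complex",
    "make_toy_antibody",
    "claudin19_topology",
    "ONE_TO_THREE",
]

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.8, 110.4
_D_CB = -122.6  # improper C-N-CA-CB for L-amino acids


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural extension reference frame: position d from internal coordinates."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_extended_peptide(sequence: str, chain_id: str = "A", label: str = "peptide") -> Molecule:
    """Backbone-only peptide (N, CA, C, O, CB except Gly) with φ = ψ = ω = 180°.

    Ideal bond geometry gives the trans-extended chain its characteristic
    consecutive Cα–Cα distance of ~3.80 Å. Residues are numbered from 1.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    for letter in sequence:
        if letter not in ONE_TO_THREE:
            raise ValueError(f"unknown residue code {letter!r}")
    phi = psi = omega = 180.0
    atoms: list[Atom] = []
    serial = 1
    n_prev = ca_prev = c_prev = None
    for i, letter in enumerate(sequence):
        resname = ONE_TO_THREE[letter]
        if i == 0:
            n = np.array([0.0, 0.0, 0.0])
            ca = np.array([_B_N_CA, 0.0, 0.0])
            angle = np.deg2rad(_A_N_CA_C)
            c = ca + _B_CA_C * np.array([-np.cos(angle), np.sin(angle), 0.0])
        else:
            n = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
            ca = _place_atom(ca_prev, c_prev, n, _B_N_CA, _A_C_N_CA, omega)
            c = _place_atom(c_prev, n, ca, _B_CA_C, _A_N_CA_C, phi)
        o = _place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
        positions = [("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)]
        if resname != "GLY":
            cb = _place_atom(c, n, ca, _B_CA_CB, _A_N_CA_CB, _D_CB)
            positions.append(("CB", "C", cb))
        for name, element, xyz in positions:
            atoms.append(
                Atom(serial=serial, name=name, element=element, residue_name=resname,
                     residue_number=i + 1, insertion_code="", chain_id=chain_id, coordinates=xyz)
            )
            serial += 1
        n_prev, ca_prev, c_prev = n, ca, c
    return Molecule(atoms, label=label)


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _ca_molecule(points: np.ndarray, chain_id: str, label: str, resname: str = "ALA",
                 first_residue: int = 1) -> Molecule:
    atoms = [
        Atom(serial=i + 1, name="CA", element="C", residue_name=resname,
             residue_number=first_residue + i, insertion_code="", chain_id=chain_id,
             coordinates=p)
        for i, p in enumerate(points)
    ]
    return Molecule(atoms, label=label)


def _residue_cluster_molecule(points: np.ndarray, normals: np.ndarray, chain_id: str,
                              label: str) -> Molecule:
    """Poly-alanine pseudo-residues: CA at each lattice point plus N/C offset
    tangentially and O inward, so the surface is solid at atomic resolution."""
    atoms: list[Atom] = []
    serial = 1
    for i, (p, u) in enumerate(zip(points, normals)):
        t1 = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(u, [1.0, 0.0, 0.0])
        t1 /= np.linalg.norm(t1)
        for name, element, xyz in (
            ("N", "N", p + 1.9 * t1),
            ("CA", "C", p),
            ("C", "C", p - 1.9 * t1),
            ("O", "O", p - 1.6 * u),
        ):
            atoms.append(Atom(serial=serial, name=name, element=element, residue_name="ALA",
                              residue_number=i + 1, insertion_code="", chain_id=chain_id,
                              coordinates=xyz))
            serial += 1
    return Molecule(atoms, label=label)


def make_toy_complex(
    seed: int = 0,
    n_receptor_residues: int = 60,
    n_ligand_residues: int = 12,
    shell_radius: float = 12.0,
    burial: float = 4.0,
    contact_distance: float = 3.8,
    interface_cutoff: float = 5.0,
    wall_layers: int = 2,
) -> tuple[Molecule, Molecule, Pose, RestraintSet]:
    """Toy receptor–ligand complex with known native pose and restraints.

    Returns (receptor, ligand, native_pose, restraints). The ligand — a
    radius-tapered helical Cα/Cβ trace with no end-to-end pseudosymmetry —
    is placed partially sunk (by ``burial`` Å) into the +z pole of a
    pseudo-protein shell, and the shell is molded around it: every lattice
    cluster that would clash is pushed radially inward until its closest
    approach to the ligand equals ``contact_distance``. ``wall_layers``
    concentric lattice shells (3.6 Å apart) are molded the same way, giving
    the groove a solid back so deeply inserted decoys clash. The native
    pose is therefore the contact-density optimum of the binding patch by
    construction, and an aperiodic set of salt bridges — lysine-like +1
    charges on six ligand residues, aspartate-like −0.5 counter-charges on
    the receptor clusters they touch — pins the binding register the way
    real interfaces do, so slid or flipped in-groove poses lose both shape
    and charge complementarity. Restraints are the residues with any
    heavy-atom pair within ``interface_cutoff`` across the native
    interface.
    """
    if n_receptor_residues < 4 or n_ligand_residues < 4:
        raise ValueError("toy complex sizes must be at least 4 residues")
    rng = np.random.default_rng(seed)
    directions = _fibonacci_sphere(n_receptor_residues)
    directions += rng.normal(0.0, 0.004, size=directions.shape)
    directions /= np.linalg.norm(directions, axis=1)[:, None]

    # helix-like Calpha trace, axis along x, plus a CB per residue pointing
    # away from the axis; sunk `burial` below the shell top. The radius
    # tapers along the chain so the fragment has no end-to-end
    # pseudosymmetry: the flipped pose cannot fit the molded groove.
    turn = np.deg2rad(100.0)
    i = np.arange(n_ligand_residues)
    taper = 1.6 + 1.4 * i / (n_ligand_residues - 1)
    helix = np.column_stack(
        [1.5 * i - 1.5 * (n_ligand_residues - 1) / 2.0,
         taper * np.cos(turn * i),
         taper * np.sin(turn * i)]
    )
    side = helix.copy()
    lateral = helix[:, 1:] / np.linalg.norm(helix[:, 1:], axis=1)[:, None]
    side[:, 1:] += 1.5 * lateral
    coords = np.empty((2 * n_ligand_residues, 3))
    coords[0::2], coords[1::2] = helix, side
    coords[:, 2] += shell_radius - burial + 2.3

    def cluster_coords(direction: np.ndarray, radial: float) -> np.ndarray:
        t1 = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(direction, [1.0, 0.0, 0.0])
        t1 /= np.linalg.norm(t1)
        p = radial * direction
        return np.array([p + 1.9 * t1, p, p - 1.9 * t1, p - 1.6 * direction])

    def clearance(direction: np.ndarray, radial: float) -> float:
        cluster = cluster_coords(direction, radial)
        return float(np.min(np.linalg.norm(cluster[:, None, :] - coords[None, :, :], axis=2)))

    def molded_radial(u: np.ndarray, start: float) -> float:
        if clearance(u, start) >= contact_distance:
            return start
        s = start
        while s > 2.0 and clearance(u, s) < contact_distance:
            s -= 0.25
        lo_s, hi_s = s, s + 0.25
        for _ in range(30):  # largest radial with clearance == contact_distance
            mid = 0.5 * (lo_s + hi_s)
            if clearance(u, mid) >= contact_distance:
                lo_s = mid
            else:
                hi_s = mid
        return lo_s

    points: list[np.ndarray] = []
    normals: list[np.ndarray] = []
    for layer in range(wall_layers):
        layer_radius = shell_radius - 3.6 * layer
        for u in directions:
            points.append(molded_radial(u, layer_radius) * u)
            normals.append(u)
    receptor = _residue_cluster_molecule(np.array(points), np.array(normals),
                                         chain_id="A", label="toy-receptor")

    # aperiodic salt bridges pinning the binding register: +1 on six
    # ligand side chains, -0.5 carboxylate-like partners on the receptor
    charged = [r for r in (0, 2, 4, 6, 9, n_ligand_residues - 1) if r < n_ligand_residues]
    lig_atoms = []
    for r in range(n_ligand_residues):
        resname, side_name = ("LYS", "NZ") if r in charged else ("ALA", "CB")
        lig_atoms.append(Atom(serial=2 * r + 1, name="CA", element="C", residue_name=resname,
                              residue_number=r + 1, insertion_code="", chain_id="B",
                              coordinates=coords[2 * r]))
        lig_atoms.append(Atom(serial=2 * r + 2, name=side_name,
                              element="N" if r in charged else "C", residue_name=resname,
                              residue_number=r + 1, insertion_code="", chain_id="B",
                              coordinates=coords[2 * r + 1]))
    ligand = Molecule(lig_atoms, label="toy-ligand")
    layer1 = np.array(points[:n_receptor_residues])
    axis_z = shell_radius - burial + 2.3  # helix axis height
    lig_coords = np.array([a.coordinates for a in lig_atoms])
    serial = len(receptor.atoms)
    for r in charged:
        nz = coords[2 * r + 1]
        k = int(np.argmin(np.linalg.norm(layer1 - nz, axis=1)))
        for atom in receptor.atoms:
            if atom.residue_number == k + 1:
                atom.residue_name = "ASP"
        # counter-charge radially outward from the helix axis, beyond the NZ,
        # i.e. embedded in the molded wall and clear of the rest of the ligand
        outward = np.array([0.0, nz[1], nz[2] - axis_z])
        outward /= np.linalg.norm(outward)
        od1 = nz + 3.3 * outward
        if np.min(np.linalg.norm(lig_coords - od1, axis=1)) < 3.2:
            raise RuntimeError("toy-complex construction: counter-charge clashes with ligand")
        serial += 1
        receptor.atoms.append(Atom(serial=serial, name="OD1", element="O", residue_name="ASP",
                                   residue_number=k + 1, insertion_code="", chain_id="A",
                                   coordinates=od1))
    receptor = Molecule(receptor.atoms, label="toy-receptor")

    native_pose = Pose(translation=ligand.centroid())
    rec_coords = receptor.heavy_coordinates()
    lig_coords = ligand.heavy_coordinates()
    cross = np.linalg.norm(rec_coords[:, None, :] - lig_coords[None, :, :], axis=2)
    rec_contacts = np.flatnonzero(cross.min(axis=1) <= interface_cutoff)
    lig_contacts = np.flatnonzero(cross.min(axis=0) <= interface_cutoff)
    restraints = RestraintSet(
        receptor=[receptor.atoms[j].residue_ref for j in rec_contacts],
        ligand=[ligand.atoms[j].residue_ref for j in lig_contacts],
    )
    return receptor, ligand, native_pose, restraints


def make_toy_antibody(n_heavy: int = 110, n_light: int = 107) -> Molecule:
    """Synthetic Fv-like poly-alanine Cα pair of chains H and L.

    Residue numbering runs 1..n per chain so that the canonical CDR windows
    of every scheme are structurally present. Geometry is a pair of loose
    coils — adequate for numbering-based CDR detection and swarm filtering,
    not a real immunoglobulin fold (synthetic stand-in).
    """
    def coil(n: int, offset: np.ndarray) -> np.ndarray:
        i = np.arange(n)
        return np.column_stack(
            [8.0 * np.cos(0.35 * i), 8.0 * np.sin(0.35 * i), 1.2 * i]
        ) + offset

    h = _ca_molecule(coil(n_heavy, np.zeros(3)), chain_id="H", label="H")
    l = _ca_molecule(coil(n_light, np.array([18.0, 0.0, 0.0])), chain_id="L", label="L")
    atoms = h.atoms + l.atoms
    for serial, atom in enumerate(atoms, start=1):
        atom.serial = serial
    return Molecule(atoms, kind=MoleculeKind.ANTIBODY, label="toy-antibody")


def claudin19_topology() -> str:
    """Membrane topology annotation of Claudin-19 (UniProt-derived segment
    table): four transmembrane helices and five extramembranous regions
    (three cytoplasmic, two extracellular)."""
    return (
        "cytoplasmic 1-7\n"
        "transmembrane 8-28\n"
        "extracellular 29-81\n"
        "transmembrane 82-102\n"
        "cytoplasmic 103-117\n"
        "transmembrane 118-138\n"
        "extracellular 139-160\n"
        "transmembrane 161-181\n"
        "cytoplasmic 182-224\n"
    )
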