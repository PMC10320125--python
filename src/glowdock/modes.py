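"""Dedicated docking modes: antibody CDR restraints and explicit membranes.

Antibody mode turns the six complementarity-determining regions (CDR loops)
of an Fv into receptor-side residue restraints, located purely from residue
numbering under a recognized scheme (Kabat, Chothia or IMGT). The input
antibody must already be numbered consistently with the chosen scheme and
must use chain ids H and L for the heavy and light chains. The window
tables live in ``data/cdr_windows.json`` so scheme corrections do not
require touching code; residues with insertion codes inside a window are
included.

Membrane mode consumes a coarse-grained lipid headgroup plane: phosphate
(PO4) beads renamed to atom ``BJ`` in residue ``MMB``. The bead z-extrema
define a slab that the swarm filter excludes. When no experimentally derived
membrane is available, :func:`build_membrane` synthesizes a single planar
bead layer at the z-height of a user-chosen anchor residue's Cα, covering
the receptor's xy footprint plus a margin, with beads clashing with the
receptor omitted. The receptor must already be oriented with the membrane
normal along z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .structures import (
    MEMBRANE_BEAD_NAME,
    MEMBRANE_RESIDUE,
    Atom,
    Molecule,
    MoleculeKind,
    ResidueRef,
    RestraintSet,
)

__all__ = [
    "CDRDefinition",
    "MembraneModel",
    "load_cdr_windows",
    "detect_cdr_restraints",
    "parse_membrane_beads",
    "build_membrane",
]

SCHEMES = ("kabat", "chothia", "imgt")


@dataclass(frozen=True)
class CDRDefinition:
    """One CDR loop window: scheme, chain (H/L), loop name, residue range."""

    scheme: str
    chain: str
    loop: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("CDR window start must not exceed end")


def load_cdr_windows(scheme: str) -> list[CDRDefinition]:
    """CDR windows for a numbering scheme, from the packaged table."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown numbering scheme {scheme!r}; choose from {SCHEMES}")
    table = json.loads(resources.files("glowdock.data").joinpath("cdr_windows.json").read_text())
    return [
        CDRDefinition(scheme, chain, loop, start, end)
        for chain, loops in table[scheme].items()
        for loop, (start, end) in loops.items()
    ]


def detect_cdr_restraints(antibody: Molecule, scheme: str = "chothia") -> RestraintSet:
    """Receptor-side restraints from every structurally present CDR residue.

    A residue belongs to a CDR when its (chain, number) falls inside one of
    the scheme's six windows; insertion-coded residues inside a window count.
    """
    chains = set(antibody.chain_ids)
    if not {"H", "L"} <= chains:
        raise ValueError("antibody must have chains H and L")
    windows = load_cdr_windows(scheme)
    refs: list[ResidueRef] = []
    for ref in antibody.residue_index:
        for w in windows:
            if ref.chain_id == w.chain and w.start <= ref.residue_number <= w.end:
                refs.append(ref)
                break
    if not refs:
        raise ValueError(f"numbering scheme mismatch: no CDR residues found for scheme {scheme!r}")
    return RestraintSet(receptor=refs)


@dataclass
class MembraneModel:
    """Coarse-grained membrane: bead positions and the slab z-bounds."""

    beads: np.ndarray
    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        self.beads = np.atleast_2d(np.asarray(self.beads, dtype=float))
        if self.beads.size == 0:
            raise ValueError("no membrane beads found")


def parse_membrane_beads(molecule: Molecule) -> MembraneModel:
    """Extract MMB/BJ beads from a molecule; non-bead atoms are ignored."""
    beads = np.array(
        [
            atom.coordinates
            for atom in molecule.atoms
            if atom.residue_name == MEMBRANE_RESIDUE and atom.name == MEMBRANE_BEAD_NAME
        ]
    )
    if beads.size == 0:
        raise ValueError("no membrane beads found")
    return MembraneModel(beads=beads, z_min=float(beads[:, 2].min()), z_max=float(beads[:, 2].max()))


def build_membrane(
    receptor: Molecule,
    anchor: ResidueRef,
    spacing: float = 5.0,
    margin: float = 20.0,
    clash_distance: float = 3.0,
) -> tuple[MembraneModel, Molecule]:
    """Synthesize a planar bead layer anchored at a residue's Cα z-height.

    The square grid covers the receptor xy bounding box expanded by
    ``margin``; beads within ``clash_distance`` of any receptor heavy atom
    are omitted. Returns the model plus a bead-only molecule (residue MMB,
    atom BJ, chain M) that can be appended to the receptor PDB file.
    """
    try:
        indices = receptor.residue_atom_indices(anchor)
    except KeyError:
        raise ValueError(f"unknown anchor residue {anchor}") from None
    anchor_atoms = [receptor.atoms[i] for i in indices]
    ca = next((a for a in anchor_atoms if a.name == "CA"), anchor_atoms[0])
    z_plane = float(ca.coordinates[2])
    heavy = receptor.heavy_coordinates()
    x_lo, y_lo = heavy[:, :2].min(axis=0) - margin
    x_hi, y_hi = heavy[:, :2].max(axis=0) + margin
    xs = np.arange(x_lo, x_hi + spacing / 2.0, spacing)
    ys = np.arange(y_lo, y_hi + spacing / 2.0, spacing)
    grid = np.array([(x, y, z_plane) for x in xs for y in ys])
    if clash_distance > 0:
        tree = cKDTree(heavy)
        dmin, _ = tree.query(grid, k=1)
        grid = grid[dmin >= clash_distance]
    if len(grid) == 0:
        raise ValueError("no membrane beads found: receptor footprint covers the whole grid")
    atoms = [
        Atom(
            serial=i + 1,
            name=MEMBRANE_BEAD_NAME,
            element=MEMBRANE_BEAD_NAME,
            residue_name=MEMBRANE_RESIDUE,
            residue_number=i + 1,
            insertion_code="",
            chain_id="M",
            coordinates=p,
        )
        for i, p in enumerate(grid)
    ]
    beads = Molecule(atoms, kind=MoleculeKind.MEMBRANE_BEADS, label="membrane")
    model = MembraneModel(beads=grid, z_min=z_plane, z_max=z_plane)
    return model, beads
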