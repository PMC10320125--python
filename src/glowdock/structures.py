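"""Structure I/O and annotation parsing.

Reads and writes fixed-column PDB files into a flat, order-preserving
:class:`Molecule` container, auto-detects the molecule kind (protein, peptide,
DNA, mixed, membrane beads), and parses the two plain-text annotation formats
used to drive a docking run: residue restraints (``<chain>.<number>`` tokens)
and membrane topology segments (``transmembrane 8-28`` lines).

Parsing rules:

* only the first MODEL of a multi-model file is read;
* alternate locations: only altloc ``' '`` or ``'A'`` atoms are kept;
* HETATM records are dropped unless the residue name is ``MMB`` (coarse-grained
  membrane beads, atom name ``BJ``);
* the element is taken from columns 77-78 when present, otherwise inferred
  from the atom name.

Hydrogens are parsed and stored but excluded from scoring and contact
computations downstream (heavy-atom docking).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np

__all__ = [
    "Atom",
    "Molecule",
    "MoleculeKind",
    "ResidueRef",
    "RestraintSet",
    "TopologySegment",
    "TopologyAnnotation",
    "read_pdb",
    "write_pdb",
    "detect_molecule_kind",
    "parse_restraints",
    "parse_topology",
    "STANDARD_AMINO_ACIDS",
    "DNA_RESIDUES",
    "MEMBRANE_RESIDUE",
    "MEMBRANE_BEAD_NAME",
]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
DNA_RESIDUES = frozenset({"DA", "DC", "DG", "DT"})
MEMBRANE_RESIDUE = "MMB"
MEMBRANE_BEAD_NAME = "BJ"

# Elements plausibly found in the two-letter atom-name column of biomolecular
# PDB files; used only when columns 77-78 are blank.
_TWO_LETTER_ELEMENTS = frozenset(
    {"FE", "ZN", "MG", "MN", "CU", "NI", "CO", "SE", "BR", "CL", "NA", "CA_ION"}
)

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "SE": 78.971,
}


class MoleculeKind(str, Enum):
    """Receptor/ligand molecule categories the pipeline distinguishes."""

    PROTEIN = "protein"
    PEPTIDE = "peptide"
    DNA = "dna"
    PROTEIN_DNA = "protein_dna"
    ANTIBODY = "antibody"
    MEMBRANE_PROTEIN = "membrane_protein"
    MEMBRANE_BEADS = "membrane_beads"


@dataclass
class Atom:
    """One atomic record with docking parameters attached lazily.

    ``charge``/``radius``/``mass`` are placeholders until
    :func:`glowdock.scoring.assign_parameters` fills them in.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    coordinates: np.ndarray
    charge: float = 0.0
    radius: float = 1.8
    mass: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"atom {self.serial} ({self.name}): coordinates must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def residue_ref(self) -> "ResidueRef":
        return ResidueRef(self.chain_id, self.residue_number, self.insertion_code)


@dataclass(frozen=True, order=True)
class ResidueRef:
    """A residue identified by chain, number and optional insertion code."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise ValueError("restraint chain id must be non-empty")

    def __str__(self) -> str:
        return f"{self.chain_id}.{self.residue_number}{self.insertion_code}"


@dataclass
class RestraintSet:
    """Receptor- and ligand-side interface residue restraints.

    Ligand-only restraints are rejected: with no receptor-side information the
    swarm filter cannot act and sampling effort would be wasted (the user
    should swap receptor and ligand instead).
    """

    receptor: list[ResidueRef] = field(default_factory=list)
    ligand: list[ResidueRef] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ligand and not self.receptor:
            raise ValueError("ligand-only restraints not allowed")

    def __bool__(self) -> bool:
        return bool(self.receptor or self.ligand)


class Molecule:
    """An ordered atomic structure with chains/residues and a detected kind.

    Atom order is exactly the input-file order; residues are contiguous runs
    of atoms sharing (chain, number, insertion code).
    """

    def __init__(self, atoms: Iterable[Atom], kind: MoleculeKind | None = None, label: str = ""):
        self.atoms: list[Atom] = list(atoms)
        if not self.atoms:
            raise ValueError("no atoms")
        self.label = label
        self._residue_index: dict[ResidueRef, list[int]] | None = None
        self.kind = kind if kind is not None else detect_molecule_kind(self)

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"Molecule({self.label or 'unnamed'}, {len(self.atoms)} atoms, kind={self.kind.value})"

    # -- geometry ---------------------------------------------------------

    def coordinates(self) -> np.ndarray:
        """All atom coordinates as an (N, 3) array (copy)."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    def heavy_coordinates(self) -> np.ndarray:
        return self.coordinates()[self.heavy_mask]

    def centroid(self) -> np.ndarray:
        """Centroid of heavy atoms (the rotation center used for poses)."""
        return self.heavy_coordinates().mean(axis=0)

    # -- residue access ---------------------------------------------------

    @property
    def residue_index(self) -> dict[ResidueRef, list[int]]:
        if self._residue_index is None:
            idx: dict[ResidueRef, list[int]] = {}
            for i, atom in enumerate(self.atoms):
                idx.setdefault(atom.residue_ref, []).append(i)
            self._residue_index = idx
        return self._residue_index

    def residues(self) -> Iterator[tuple[ResidueRef, list[Atom]]]:
        for ref, indices in self.residue_index.items():
            yield ref, [self.atoms[i] for i in indices]

    @property
    def n_residues(self) -> int:
        return len(self.residue_index)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for atom in self.atoms:
            if atom.chain_id not in seen:
                seen.append(atom.chain_id)
        return seen

    def residue_atom_indices(self, ref: ResidueRef) -> list[int]:
        try:
            return self.residue_index[ref]
        except KeyError:
            raise KeyError(f"unknown restraint residue {ref}") from None

    def anchor_atom_indices(self) -> list[int]:
        """Index of the positional anchor atom of each residue, in residue order.

        CA for amino acids, C1' for nucleotides; falls back to the first heavy
        atom of the residue. Used for flexibility modes and RMSD clustering.
        """
        out = []
        for ref, indices in self.residue_index.items():
            chosen = None
            for i in indices:
                if self.atoms[i].name in ("CA", "C1'"):
                    chosen = i
                    break
            if chosen is None:
                for i in indices:
                    if not self.atoms[i].is_hydrogen:
                        chosen = i
                        break
            out.append(chosen if chosen is not None else indices[0])
        return out


def _infer_element(atom_name: str, residue_name: str) -> str:
    """Infer the element from the atom-name field when columns 77-78 are blank."""
    if residue_name == MEMBRANE_RESIDUE:
        return MEMBRANE_BEAD_NAME
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element for atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two in _TWO_LETTER_ELEMENTS and len(atom_name.strip()) > 3:
        return two
    return stripped[0].upper()


def read_pdb(source: str | Path | TextIO, kind: MoleculeKind | None = None, label: str = "") -> Molecule:
    """Read a PDB file (path, text, or stream) into a :class:`Molecule`.

    Raises ``ValueError`` with message ``"no atoms"`` for empty structures and
    ``"malformed record"`` plus the line number for unparseable fields.
    ``kind`` overrides auto-detection.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        text = Path(source).read_text() if "\n" not in source and Path(source).exists() else source
    else:
        text = source.read()
    atoms: list[Atom] = []
    for lineno, line in enumerate(io.StringIO(text), start=1):
        record = line[:6].strip()
        if record == "ENDMDL":
            break  # first model only
        if record not in ("ATOM", "HETATM"):
            continue
        altloc = line[16:17]
        if altloc not in (" ", "A", ""):
            continue
        residue_name = line[17:20].strip()
        if record == "HETATM" and residue_name != MEMBRANE_RESIDUE:
            continue  # ligands/waters dropped; only membrane beads survive
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            chain_id = line[21:22]
            residue_number = int(line[22:26])
            icode = line[26:27].strip()
            xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed record at line {lineno}: {line.rstrip()!r}") from exc
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(name, residue_name)
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_name=residue_name,
                residue_number=residue_number,
                insertion_code=icode,
                chain_id=chain_id,
                coordinates=xyz,
                mass=_ELEMENT_MASSES.get(element, 0.0),
            )
        )
    if not atoms:
        raise ValueError("no atoms")
    return Molecule(atoms, kind=kind, label=label)


def write_pdb(molecule: Molecule, destination: str | Path | TextIO) -> None:
    """Write a molecule as fixed-column ATOM/HETATM records with TER/END.

    Membrane beads (residue MMB) are emitted as HETATM. Round-trips with
    :func:`read_pdb` on identity fields and coordinates to 3 decimals.
    """
    lines: list[str] = []
    prev_chain: str | None = None
    for atom in molecule.atoms:
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = atom.chain_id
        if np.any(np.abs(atom.coordinates) >= 10000.0):
            raise ValueError(f"unrepresentable coordinate for atom {atom.serial}: {atom.coordinates}")
        record = "HETATM" if atom.residue_name == MEMBRANE_RESIDUE else "ATOM"
        name = atom.name
        # 1-letter-element names start in column 14 by PDB convention
        name_field = f" {name:<3}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4}"
        x, y, z = atom.coordinates
        lines.append(
            f"{record:<6}{atom.serial:>5} {name_field} {atom.residue_name:>3} "
            f"{atom.chain_id:1}{atom.residue_number:>4}{atom.insertion_code or ' ':1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {atom.element[:2]:>2}"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)


def detect_molecule_kind(molecule: Molecule, override: MoleculeKind | None = None) -> MoleculeKind:
    """Classify a molecule from its residue names.

    Only DA/DC/DG/DT residues -> dna; only the 20 standard amino acids ->
    protein (peptide when a single chain of at most 30 residues); a mixture of
    both -> protein_dna; only MMB bead residues -> membrane_beads. A
    user-supplied ``override`` always wins. Single-letter legacy DNA residue
    names (A/C/G/T) are not recognized.
    """
    if override is not None:
        return override
    names = {atom.residue_name for atom in molecule.atoms}
    if names <= {MEMBRANE_RESIDUE}:
        return MoleculeKind.MEMBRANE_BEADS
    has_aa = bool(names & STANDARD_AMINO_ACIDS)
    has_dna = bool(names & DNA_RESIDUES)
    unknown = names - STANDARD_AMINO_ACIDS - DNA_RESIDUES - {MEMBRANE_RESIDUE}
    if unknown or not (has_aa or has_dna):
        raise ValueError(f"unknown molecule type: unrecognized residue names {sorted(unknown)}")
    if has_aa and has_dna:
        return MoleculeKind.PROTEIN_DNA
    if has_dna:
        return MoleculeKind.DNA
    if len(molecule.chain_ids) == 1 and molecule.n_residues <= 30:
        return MoleculeKind.PEPTIDE
    return MoleculeKind.PROTEIN


_RESTRAINT_TOKEN = re.compile(r"^(?P<chain>[^.\s]+)\.(?P<num>\d+)(?P<icode>[A-Za-z]?)$")


def _parse_restraint_tokens(text: str) -> list[ResidueRef]:
    refs: list[ResidueRef] = []
    for token in re.split(r"[\s,]+", text.strip()):
        if not token:
            continue
        m = _RESTRAINT_TOKEN.match(token)
        if m is None:
            raise ValueError(f"malformed restraint {token!r} (expected <chain>.<residue number>)")
        ref = ResidueRef(m["chain"], int(m["num"]), m["icode"].upper())
        if ref not in refs:
            refs.append(ref)
    return refs


def parse_restraints(receptor_text: str, ligand_text: str = "") -> RestraintSet:
    """Parse whitespace/comma-separated ``<chain>.<number>[icode]`` tokens.

    Duplicates are dropped keeping first occurrence; ligand restraints without
    any receptor restraint are rejected.
    """
    receptor = _parse_restraint_tokens(receptor_text)
    ligand = _parse_restraint_tokens(ligand_text)
    return RestraintSet(receptor=receptor, ligand=ligand)


class SegmentKind(str, Enum):
    TRANSMEMBRANE = "transmembrane"
    CYTOPLASMIC = "cytoplasmic"
    EXTRACELLULAR = "extracellular"


@dataclass(frozen=True)
class TopologySegment:
    kind: SegmentKind
    start: int
    end: int


@dataclass
class TopologyAnnotation:
    """Membrane topology: an ordered list of non-overlapping residue segments."""

    segments: list[TopologySegment]

    @property
    def transmembrane(self) -> list[TopologySegment]:
        return [s for s in self.segments if s.kind is SegmentKind.TRANSMEMBRANE]

    @property
    def extramembranous(self) -> list[TopologySegment]:
        return [s for s in self.segments if s.kind is not SegmentKind.TRANSMEMBRANE]


def parse_topology(text: str) -> TopologyAnnotation:
    """Parse ``<kind> <start>-<end>`` lines (hyphen or en-dash) into segments.

    Kinds are transmembrane / cytoplasmic / extracellular. Overlapping
    segments or start > end raise ``ValueError("inconsistent topology")``.
    """
    segments: list[TopologySegment] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed topology line {lineno}: {line!r}")
        kind_word, span = parts
        try:
            kind = SegmentKind(kind_word.lower())
        except ValueError:
            raise ValueError(f"unknown segment kind {kind_word!r} at line {lineno}") from None
        m = re.match(r"^(\d+)[-–](\d+)$", span)
        if m is None:
            raise ValueError(f"malformed topology line {lineno}: {line!r}")
        start, end = int(m.group(1)), int(m.group(2))
        if start > end:
            raise ValueError(f"inconsistent topology: segment {start}-{end} has start > end")
        segments.append(TopologySegment(kind, start, end))
    spans = sorted((s.start, s.end) for s in segments)
    for (s1, e1), (s2, _) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"inconsistent topology: segments overlap near residue {s2}")
    return TopologyAnnotation(segments)
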