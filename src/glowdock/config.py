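"""Run configuration and the supported receptor–ligand scenarios.

Nine receptor–ligand molecule-type scenarios are supported; the membrane
scenario disables receptor flexibility (an explicit membrane pins the
receptor frame, and elastic-network deformation of a membrane-embedded
receptor would break the slab geometry the swarm filter relies on).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .structures import MoleculeKind

__all__ = ["ScenarioDescriptor", "enumerate_modes", "RunConfig"]


@dataclass(frozen=True)
class ScenarioDescriptor:
    """One supported receptor–ligand molecule-type combination."""

    name: str
    receptor_kind: MoleculeKind
    ligand_kind: MoleculeKind
    receptor_flexibility_allowed: bool = True


def enumerate_modes() -> list[ScenarioDescriptor]:
    """The nine supported receptor–ligand scenarios."""
    K = MoleculeKind
    return [
        ScenarioDescriptor("protein-protein", K.PROTEIN, K.PROTEIN),
        ScenarioDescriptor("protein-protein+dna", K.PROTEIN, K.PROTEIN_DNA),
        ScenarioDescriptor("protein-dna", K.PROTEIN, K.DNA),
        ScenarioDescriptor("protein+dna-protein", K.PROTEIN_DNA, K.PROTEIN),
        ScenarioDescriptor("dna-protein", K.DNA, K.PROTEIN),
        ScenarioDescriptor(
            "membrane_protein-protein", K.MEMBRANE_PROTEIN, K.PROTEIN,
            receptor_flexibility_allowed=False,
        ),
        ScenarioDescriptor("antibody-protein", K.ANTIBODY, K.PROTEIN),
        ScenarioDescriptor("antibody-protein+dna", K.ANTIBODY, K.PROTEIN_DNA),
        ScenarioDescriptor("antibody-dna", K.ANTIBODY, K.DNA),
    ]


_MODE_NAMES = [s.name for s in enumerate_modes()]


@dataclass
class RunConfig:
    """Everything needed to reproduce a docking run.

    ``seed`` is mandatory: there is no silent nondeterminism. ``top_n`` is 5
    or 10 (the number of delivered model PDBs). A membrane receptor forces
    ``receptor_flexible`` off.
    """

    mode: str = "protein-protein"
    seed: int = 0
    steps: int = 100
    swarms: int | None = None  # override of the dynamic swarm count
    glowworms: int = 200
    receptor_flexible: bool = False
    ligand_flexible: bool = False
    n_modes: int = 10
    scoring: str = "default"
    scoring_params: dict = field(default_factory=dict)
    receptor_restraints: str = ""  # restraint tokens or a file path
    ligand_restraints: str = ""
    top_n: int = 5
    min_fsat: float = 0.5
    scheme: str = "chothia"  # antibody numbering scheme
    swarm_radius: float = 10.0
    placement_distance: float = 10.0
    density_spacing: float = 10.0
    keep_cutoff: float = 20.0
    membrane_cushion: float = 5.0
    rmsd_cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.mode not in _MODE_NAMES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {_MODE_NAMES}")
        if self.top_n not in (5, 10):
            raise ValueError("top_n must be 5 or 10")
        if self.scenario.receptor_kind is MoleculeKind.MEMBRANE_PROTEIN and self.receptor_flexible:
            warnings.warn("membrane receptor: receptor flexibility forced off", stacklevel=2)
            self.receptor_flexible = False

    @property
    def scenario(self) -> ScenarioDescriptor:
        return next(s for s in enumerate_modes() if s.name == self.mode)

    # -- (de)serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))
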