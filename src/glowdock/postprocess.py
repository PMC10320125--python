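"""Clustering, ranking, restraint filtering and report writing.

After optimization, each swarm's glowworms are clustered with a one-pass
BSAS (basic sequential algorithmic scheme) on the ligand anchor-atom RMSD
(Cα for proteins, C1' for DNA), visiting agents by descending luciferin so
cluster representatives are the locally best-converged poses. Cluster
representatives from all swarms are then ranked globally by their raw score
— the restraint bias shapes the search, but reported energies are the
physical ones — and optionally filtered by restraint satisfaction so every
delivered model agrees with the declared interface data.

A final relaxation hook is exposed for plugging in a geometry-refinement
backend; the default is the identity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gso import Glowworm
from .pose import ModeBasis, Pose, apply_pose
from .structures import Molecule, RestraintSet, write_pdb

__all__ = [
    "RankedModel",
    "ligand_rmsd",
    "cluster_swarm",
    "rank_models",
    "filter_models_by_restraints",
    "write_report",
    "relax_models",
]


@dataclass
class RankedModel:
    """A final pose with score, restraint satisfaction and provenance."""

    rank: int
    swarm_id: int
    glowworm_id: int
    score: float
    f_sat: float
    cluster_id: int
    pose: Pose


def ligand_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD without superposition (both poses live in the receptor frame)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def cluster_swarm(
    glowworms: list[Glowworm],
    ligand: Molecule,
    rmsd_cutoff: float = 4.0,
    basis: ModeBasis | None = None,
) -> dict[int, int]:
    """BSAS clustering of a swarm's poses on anchor-atom RMSD.

    Glowworms are visited by descending luciferin (ties by ascending id). A
    glowworm founds a new cluster iff its RMSD to every existing cluster
    representative exceeds the cutoff; otherwise it joins the nearest
    representative's cluster. Representatives are the founders. Returns
    glowworm id -> cluster id.
    """
    if not glowworms:
        raise ValueError("cluster_swarm requires at least one glowworm")
    anchors = ligand.anchor_atom_indices()
    order = sorted(glowworms, key=lambda g: (-g.luciferin, g.id))
    representatives: list[np.ndarray] = []
    assignment: dict[int, int] = {}
    for agent in order:
        coords = apply_pose(ligand, agent.pose, basis)[anchors]
        if representatives:
            rmsds = np.array([ligand_rmsd(coords, rep) for rep in representatives])
            nearest = int(np.argmin(rmsds))
            if rmsds[nearest] <= rmsd_cutoff:
                assignment[agent.id] = nearest
                continue
        representatives.append(coords)
        assignment[agent.id] = len(representatives) - 1
    return assignment


def rank_models(models: list[RankedModel]) -> list[RankedModel]:
    """Sort by raw score descending, ties by (swarm, glowworm); re-rank 1..N."""
    if not models:
        raise ValueError("rank_models requires at least one model")
    ordered = sorted(models, key=lambda m: (-m.score, m.swarm_id, m.glowworm_id))
    for rank, model in enumerate(ordered, start=1):
        model.rank = rank
    return ordered


def filter_models_by_restraints(
    models: list[RankedModel],
    restraints: RestraintSet | None,
    min_fsat: float = 0.5,
) -> list[RankedModel]:
    """Keep models with f_sat >= min_fsat and re-rank survivors.

    A no-op without restraints. Zero survivors is a warning, not an error:
    an empty report is a legitimate (if disappointing) outcome.
    """
    if restraints is None or not restraints:
        return list(models)
    kept = [m for m in models if m.f_sat >= min_fsat]
    if not kept:
        warnings.warn("all models violate the restraints; empty report", stacklevel=2)
        return []
    return rank_models(kept)


def relax_models(models: list[RankedModel], backend=None) -> list[RankedModel]:
    """Final-relaxation hook (plug-in contract).

    A backend takes and returns the model list, refining geometries in
    place; with no backend this is the identity, and the docking poses are
    delivered unrelaxed.
    """
    if backend is None:
        return models
    return backend(models)


def write_report(
    models: list[RankedModel],
    receptor: Molecule,
    ligand: Molecule,
    out_dir: str | Path,
    top_n: int = 5,
    basis: ModeBasis | None = None,
    run_config: dict | None = None,
) -> list[Path]:
    """Write ``rank.tsv`` for all models and ``model_<rank>.pdb`` for the top ones.

    Model PDBs contain the receptor plus the posed ligand under a distinct
    chain id. Returns the written paths; ``run_config`` is echoed to
    ``run_config.json`` when given.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tsv = out_dir / "rank.tsv"
    with tsv.open("w") as fh:
        fh.write("rank\tswarm\tglowworm\tscore\tf_sat\tcluster\n")
        for m in models:
            fh.write(
                f"{m.rank}\t{m.swarm_id}\t{m.glowworm_id}\t{m.score:.6f}\t{m.f_sat:.4f}\t{m.cluster_id}\n"
            )
    written.append(tsv)
    used_chains = set(receptor.chain_ids)
    ligand_chain = next(c for c in "BCDEFGHIJKLMNOPQRSTUVWXYZA" if c not in used_chains)
    for m in models[:top_n]:
        coords = apply_pose(ligand, m.pose, basis)
        atoms = [
            type(a)(
                serial=a.serial, name=a.name, element=a.element,
                residue_name=a.residue_name, residue_number=a.residue_number,
                insertion_code=a.insertion_code, chain_id=a.chain_id,
                coordinates=a.coordinates.copy(),
            )
            for a in receptor.atoms
        ]
        offset = max(a.serial for a in receptor.atoms)
        for i, a in enumerate(ligand.atoms):
            atoms.append(
                type(a)(
                    serial=offset + i + 1, name=a.name, element=a.element,
                    residue_name=a.residue_name, residue_number=a.residue_number,
                    insertion_code=a.insertion_code, chain_id=ligand_chain,
                    coordinates=coords[i],
                )
            )
        path = out_dir / f"model_{m.rank}.pdb"
        write_pdb(Molecule(atoms, kind=receptor.kind, label=f"model_{m.rank}"), path)
        written.append(path)
    if run_config is not None:
        cfg = out_dir / "run_config.json"
        cfg.write_text(json.dumps(run_config, indent=2, sort_keys=True) + "\n")
        written.append(cfg)
    return written
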