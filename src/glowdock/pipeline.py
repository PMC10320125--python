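"""End-to-end docking orchestration: setup → optimize → rank.

The in-memory entry point is :func:`dock`; the file-based stages
(:func:`setup_run`, :func:`run_optimization`, :func:`rank_run`) mirror the
three-step submission flow of the CLI and exchange plain-text swarm files
(``init/swarm_<i>.txt``, one tab-separated glowworm per line).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import RunConfig
from .gso import Glowworm, GSOParameters, run_swarm
from .modes import MembraneModel, detect_cdr_restraints
from .postprocess import (
    RankedModel,
    cluster_swarm,
    filter_models_by_restraints,
    rank_models,
    relax_models,
    write_report,
)
from .pose import ModeBasis, Pose, compute_anm_basis
from .sampling import (
    Swarm,
    filter_swarms_by_membrane,
    filter_swarms_by_restraints,
    generate_swarms,
    init_glowworms,
)
from .scoring import ScoringParameters, get_scoring
from .structures import Molecule, MoleculeKind, RestraintSet

logger = logging.getLogger("glowdock")

__all__ = ["DockingResult", "dock", "save_swarm", "load_swarm", "setup_run", "run_optimization", "rank_run"]


@dataclass
class DockingResult:
    """Everything a run produces: swarms, traces, and the ranked models."""

    swarms: list[Swarm]
    models: list[RankedModel]
    traces: dict[int, list[float]]
    restraints: RestraintSet | None

    @property
    def best(self) -> RankedModel | None:
        return self.models[0] if self.models else None


def _gso_params(config: RunConfig) -> GSOParameters:
    return GSOParameters(steps=config.steps, r_s=2.0 * config.swarm_radius)


def _prepare_swarms(receptor: Molecule, config: RunConfig, restraints, membrane) -> list[Swarm]:
    """Generate and filter swarms; apply the user swarm-count override last.

    The override is applied after restraint/membrane filtering so that a
    small requested count still samples the declared interface: densify the
    lattice when more swarms are wanted, subsample evenly when fewer.
    """
    def build(n: int | None) -> list[Swarm]:
        swarms = generate_swarms(
            receptor,
            placement_distance=config.placement_distance,
            swarm_radius=config.swarm_radius,
            density_spacing=config.density_spacing,
            seed=config.seed,
            n_swarms=n,
        )
        swarms = filter_swarms_by_restraints(swarms, receptor, restraints, config.keep_cutoff)
        if membrane is not None:
            swarms = filter_swarms_by_membrane(swarms, membrane, config.membrane_cushion)
        return swarms

    swarms = build(None)
    if config.swarms is None or config.swarms == len(swarms):
        return swarms
    if config.swarms > len(swarms):
        swarms = build(config.swarms)
        if config.swarms >= len(swarms):
            return swarms
    if restraints is not None and restraints.receptor:
        # with a declared interface, a reduced budget goes to the swarms
        # closest to the restraint patch
        anchor = np.vstack([
            np.array([receptor.atoms[i].coordinates
                      for i in receptor.residue_atom_indices(ref)])
            for ref in restraints.receptor
        ])
        def patch_distance(s: Swarm) -> float:
            return float(np.min(np.linalg.norm(anchor - s.center, axis=1)))
        swarms = sorted(swarms, key=lambda s: (patch_distance(s), s.id))[: config.swarms]
        return sorted(swarms, key=lambda s: s.id)
    keep = np.linspace(0, len(swarms) - 1, config.swarms).round().astype(int)
    return [swarms[i] for i in keep]


def dock(
    receptor: Molecule,
    ligand: Molecule,
    config: RunConfig,
    restraints: RestraintSet | None = None,
    membrane: MembraneModel | None = None,
) -> DockingResult:
    """Run the full docking protocol in memory.

    Swarms are generated over the receptor surface, filtered by restraints
    and/or the membrane slab, populated with (possibly restraint-oriented)
    glowworms, optimized independently with one RNG stream per swarm
    (seeded ``seed + swarm_id``), clustered, ranked by raw score, and
    filtered by restraint satisfaction.
    """
    scenario = config.scenario
    if scenario.receptor_kind is MoleculeKind.ANTIBODY and (restraints is None or not restraints.receptor):
        cdr = detect_cdr_restraints(receptor, config.scheme)
        ligand_side = restraints.ligand if restraints else []
        restraints = RestraintSet(receptor=cdr.receptor, ligand=list(ligand_side))
        logger.info("antibody mode: %d CDR residues as receptor restraints", len(cdr.receptor))

    swarms = _prepare_swarms(receptor, config, restraints, membrane)
    logger.info("%d swarms after filtering", len(swarms))

    basis: ModeBasis | None = None
    if config.ligand_flexible:
        basis = compute_anm_basis(ligand, M=config.n_modes)
    M = basis.n_modes if basis is not None else 0

    params = _gso_params(config)
    scoring_params = ScoringParameters(**config.scoring_params)
    factory = get_scoring(config.scoring)
    objective = factory(receptor, ligand, params=scoring_params, restraints=restraints, basis=basis)

    traces: dict[int, list[float]] = {}
    representatives: list[RankedModel] = []
    for swarm in swarms:
        rng = np.random.default_rng((config.seed + swarm.id) % 2**31)
        init_glowworms(
            swarm, ligand, n_glowworms=config.glowworms, restraints=restraints,
            receptor=receptor, M=M, rng=rng, params=params,
        )
        _, trace = run_swarm(swarm, objective, params, rng=rng)
        traces[swarm.id] = trace
        logger.info("swarm %d: best score %.3f", swarm.id, trace[-1])
        assignment = cluster_swarm(swarm.glowworms, ligand, config.rmsd_cutoff, basis)
        by_id = {g.id: g for g in swarm.glowworms}
        seen: set[int] = set()
        order = sorted(swarm.glowworms, key=lambda g: (-g.luciferin, g.id))
        for agent in order:
            cid = assignment[agent.id]
            if cid in seen:
                continue
            seen.add(cid)
            breakdown = objective(agent.pose)
            representatives.append(
                RankedModel(
                    rank=0, swarm_id=swarm.id, glowworm_id=agent.id,
                    score=breakdown.raw, f_sat=breakdown.f_sat, cluster_id=cid,
                    pose=agent.pose,
                )
            )
    models = rank_models(representatives)
    models = filter_models_by_restraints(models, restraints, config.min_fsat)
    models = relax_models(models)
    return DockingResult(swarms=swarms, models=models, traces=traces, restraints=restraints)


# -- file-based stages -----------------------------------------------------


def save_swarm(swarm: Swarm, path: str | Path, with_scores: bool = False) -> None:
    """One glowworm per line: translation, quaternion, amplitudes (tab-separated).

    With ``with_scores`` two extra columns (luciferin, score) are appended —
    the snapshot format of the optimization stage.
    """
    lines = []
    for g in swarm.glowworms:
        fields = [*g.pose.translation, *g.pose.rotation, *g.pose.mode_amplitudes]
        if with_scores:
            fields += [g.luciferin, g.score]
        lines.append("\t".join(f"{v:.17g}" for v in fields))
    Path(path).write_text("\n".join(lines) + "\n")


def load_swarm(path: str | Path, swarm_id: int, center, radius: float, M: int = 0,
               params: GSOParameters | None = None) -> Swarm:
    params = params or GSOParameters()
    r0 = params.initial_vision if params.initial_vision is not None else params.r_s / 2.0
    glowworms = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        values = [float(v) for v in line.split("\t")]
        pose = Pose(values[:3], values[3:7], values[7 : 7 + M])
        luciferin = values[7 + M] if len(values) > 7 + M else params.ell0
        score = values[8 + M] if len(values) > 8 + M else -np.inf
        glowworms.append(Glowworm(pose=pose, luciferin=luciferin, vision_range=r0, score=score, id=i))
    return Swarm(id=swarm_id, center=np.asarray(center, dtype=float), radius=radius, glowworms=glowworms)


def _swarm_meta_path(run_dir: Path) -> Path:
    return run_dir / "init" / "swarms.tsv"


def setup_run(receptor: Molecule, ligand: Molecule, config: RunConfig, run_dir: str | Path,
              restraints: RestraintSet | None = None, membrane: MembraneModel | None = None) -> list[Swarm]:
    """Stage 1: generate/filter swarms, initialize glowworms, write init files."""
    run_dir = Path(run_dir)
    (run_dir / "init").mkdir(parents=True, exist_ok=True)
    scenario = config.scenario
    if scenario.receptor_kind is MoleculeKind.ANTIBODY and (restraints is None or not restraints.receptor):
        cdr = detect_cdr_restraints(receptor, config.scheme)
        restraints = RestraintSet(receptor=cdr.receptor, ligand=list(restraints.ligand) if restraints else [])
    swarms = _prepare_swarms(receptor, config, restraints, membrane)
    params = _gso_params(config)
    M = config.n_modes if config.ligand_flexible else 0
    meta_lines = ["id\tcx\tcy\tcz\tradius"]
    for swarm in swarms:
        rng = np.random.default_rng((config.seed + swarm.id) % 2**31)
        init_glowworms(swarm, ligand, n_glowworms=config.glowworms, restraints=restraints,
                       receptor=receptor, M=M, rng=rng, params=params)
        save_swarm(swarm, run_dir / "init" / f"swarm_{swarm.id}.txt")
        cx, cy, cz = swarm.center
        meta_lines.append(f"{swarm.id}\t{cx:.6f}\t{cy:.6f}\t{cz:.6f}\t{swarm.radius}")
    _swarm_meta_path(run_dir).write_text("\n".join(meta_lines) + "\n")
    config.to_json(run_dir / "run_config.json")
    return swarms


def run_optimization(receptor: Molecule, ligand: Molecule, config: RunConfig, run_dir: str | Path,
                     restraints: RestraintSet | None = None, save_every: int | None = None) -> list[Swarm]:
    """Stage 2: load init files, run GSO per swarm, write final snapshots.

    The movement RNG continues the per-swarm stream used at initialization,
    so setup+run equals the in-memory :func:`dock` trajectory.
    """
    run_dir = Path(run_dir)
    params = _gso_params(config)
    basis = compute_anm_basis(ligand, M=config.n_modes) if config.ligand_flexible else None
    M = basis.n_modes if basis is not None else 0
    scoring_params = ScoringParameters(**config.scoring_params)
    objective = get_scoring(config.scoring)(
        receptor, ligand, params=scoring_params, restraints=restraints, basis=basis
    )
    swarms = []
    meta = _swarm_meta_path(run_dir).read_text().splitlines()[1:]
    for line in meta:
        sid, cx, cy, cz, radius = line.split("\t")
        swarm = load_swarm(run_dir / "init" / f"swarm_{sid}.txt", int(sid),
                           (float(cx), float(cy), float(cz)), float(radius), M, params)
        rng = np.random.default_rng((config.seed + swarm.id) % 2**31)
        # replay the initialization draws so the movement stream matches dock()
        init_glowworms(Swarm(swarm.id, swarm.center, swarm.radius), ligand,
                       n_glowworms=config.glowworms, restraints=restraints,
                       receptor=receptor, M=M, rng=rng, params=params)
        swarm_dir = run_dir / f"swarm_{swarm.id}"
        swarm_dir.mkdir(exist_ok=True)

        def snapshot(step: int, s: Swarm, _dir=swarm_dir) -> None:
            if save_every and (step + 1) % save_every == 0:
                save_swarm(s, _dir / f"gso_{step + 1}.out", with_scores=True)

        run_swarm(swarm, objective, params, rng=rng, on_step=snapshot)
        save_swarm(swarm, swarm_dir / f"gso_{params.steps}.out", with_scores=True)
        swarms.append(swarm)
    return swarms


def rank_run(receptor: Molecule, ligand: Molecule, config: RunConfig, run_dir: str | Path,
             restraints: RestraintSet | None = None) -> list[RankedModel]:
    """Stage 3: cluster final snapshots, rank, filter, write the report."""
    run_dir = Path(run_dir)
    params = _gso_params(config)
    basis = compute_anm_basis(ligand, M=config.n_modes) if config.ligand_flexible else None
    M = basis.n_modes if basis is not None else 0
    scoring_params = ScoringParameters(**config.scoring_params)
    objective = get_scoring(config.scoring)(
        receptor, ligand, params=scoring_params, restraints=restraints, basis=basis
    )
    representatives: list[RankedModel] = []
    meta = _swarm_meta_path(run_dir).read_text().splitlines()[1:]
    for line in meta:
        sid, cx, cy, cz, radius = line.split("\t")
        sid = int(sid)
        swarm = load_swarm(run_dir / f"swarm_{sid}" / f"gso_{params.steps}.out", sid,
                           (float(cx), float(cy), float(cz)), float(radius), M, params)
        assignment = cluster_swarm(swarm.glowworms, ligand, config.rmsd_cutoff, basis)
        seen: set[int] = set()
        for agent in sorted(swarm.glowworms, key=lambda g: (-g.luciferin, g.id)):
            cid = assignment[agent.id]
            if cid in seen:
                continue
            seen.add(cid)
            breakdown = objective(agent.pose)
            representatives.append(RankedModel(0, sid, agent.id, breakdown.raw, breakdown.f_sat, cid, agent.pose))
    models = rank_models(representatives)
    models = filter_models_by_restraints(models, restraints, config.min_fsat)
    models = relax_models(models)
    write_report(models, receptor, ligand, run_dir, top_n=config.top_n, basis=basis,
                 run_config=json.loads(config.to_json()))
    return models
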