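"""Glowworm Swarm Optimization over pose space.

Each agent ("glowworm") carries a pose, a luciferin level that integrates its
objective value over time, and an adaptive vision range. One optimization
step, in order:

1. score every agent with the objective;
2. luciferin update  l <- (1 - rho) l + gamma J;
3. movement: each agent collects brighter neighbors within its vision range,
   picks one by luciferin-excess roulette, and takes a fixed-size step toward
   it in the concatenated pose metric space (translation, quaternion scaled
   by w_q, mode amplitudes);
4. vision-range update  r_d <- min(r_s, max(0, r_d + beta (n_t - |N|))).

The movement phase is synchronous: neighborhoods, targets and step vectors
are all computed from the post-update state at the start of the phase and
applied together, so results do not depend on agent iteration order. A
non-finite objective marks the agent with score -inf so it can never attract
others. One seeded generator per swarm makes runs bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pose import DEFAULT_QUATERNION_WEIGHT, Pose, canonicalize_quaternion, pose_distance

__all__ = [
    "GSOParameters",
    "Glowworm",
    "luciferin_update",
    "find_neighbors",
    "select_target",
    "move_glowworm",
    "update_vision_range",
    "run_swarm",
]


@dataclass
class GSOParameters:
    """Canonical GSO constants plus pose-space specifics.

    ``s`` is the step size in pose-metric units (Å-equivalent once rotations
    are scaled by ``w_q``); ``r_s`` defaults to twice the swarm radius when a
    swarm is available, else 20.
    """

    rho: float = 0.4  # luciferin decay in (0, 1]
    gamma: float = 0.6  # luciferin enhancement
    beta: float = 0.08  # vision-range adjustment rate
    n_t: int = 5  # desired neighbor count
    s: float = 0.5  # step size in pose-space units (~Å per iteration)
    r_s: float = 20.0  # maximum vision range
    ell0: float = 5.0  # initial luciferin
    steps: int = 100
    w_q: float = DEFAULT_QUATERNION_WEIGHT
    amplitude_bound: float = 3.0  # |nu_k| clamp for mode amplitudes
    initial_vision: float | None = None  # defaults to r_s / 2 (local neighborhoods)

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")
        for name in ("gamma", "beta", "s", "r_s", "ell0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_t <= 0 or self.steps <= 0:
            raise ValueError("n_t and steps must be positive")


@dataclass
class Glowworm:
    """One GSO agent: a pose plus luciferin, vision range and raw score."""

    pose: Pose
    luciferin: float
    vision_range: float
    score: float = -np.inf  # raw score S of the last evaluation
    id: int = 0

    def copy(self) -> "Glowworm":
        return Glowworm(self.pose.copy(), self.luciferin, self.vision_range, self.score, self.id)


def luciferin_update(ell: float, J: float, params: GSOParameters) -> float:
    """l <- (1 - rho) l + gamma J; fixed point gamma J / rho for constant J."""
    return (1.0 - params.rho) * ell + params.gamma * J


def find_neighbors(
    agent: Glowworm,
    population: list[Glowworm],
    metric=pose_distance,
) -> list[Glowworm]:
    """Strictly brighter agents strictly inside the agent's vision range."""
    return [
        other
        for other in population
        if other.id != agent.id
        and other.luciferin > agent.luciferin
        and metric(other.pose, agent.pose) < agent.vision_range
    ]


def select_target(
    agent: Glowworm,
    neighbors: list[Glowworm],
    rng: np.random.Generator,
) -> Glowworm:
    """Roulette selection with probability proportional to luciferin excess."""
    if not neighbors:
        raise ValueError("select_target requires a non-empty neighbor list")
    excess = np.array([n.luciferin - agent.luciferin for n in neighbors], dtype=float)
    infinite = np.isinf(excess)
    if infinite.any():  # agent at -inf: all brighter neighbors are equally attractive
        return neighbors[int(rng.choice(np.flatnonzero(infinite)))]
    probabilities = excess / excess.sum()
    return neighbors[int(rng.choice(len(neighbors), p=probabilities))]


def move_glowworm(agent: Glowworm, target: Glowworm, params: GSOParameters) -> Pose:
    """Step of size ``s`` toward the target in concatenated pose coordinates.

    The quaternion block is renormalized and sign-canonicalized after the
    linear step; mode amplitudes are clamped to ±amplitude_bound. Zero
    distance is a no-op.
    """
    x_i = agent.pose.as_vector(params.w_q)
    x_t = target.pose.as_vector(params.w_q)
    delta = x_t - x_i
    distance = float(np.linalg.norm(delta))
    if distance == 0.0:
        return agent.pose.copy()
    x_new = x_i + params.s * delta / distance
    translation = x_new[:3]
    quaternion = canonicalize_quaternion(x_new[3:7] / params.w_q)
    amplitudes = np.clip(x_new[7:], -params.amplitude_bound, params.amplitude_bound)
    return Pose(translation, quaternion, amplitudes)


def update_vision_range(r_d: float, n_neighbors: int, params: GSOParameters) -> float:
    """r_d <- min(r_s, max(0, r_d + beta (n_t - |N|)))."""
    return min(params.r_s, max(0.0, r_d + params.beta * (params.n_t - n_neighbors)))


def _evaluate(objective, pose: Pose) -> tuple[float, float]:
    """(raw score, optimizer objective) from either a float- or breakdown-valued objective."""
    result = objective(pose)
    if hasattr(result, "objective"):
        raw, J = float(result.raw), float(result.objective)
    else:
        raw = J = float(result)
    if not np.isfinite(J):
        return -np.inf, -np.inf
    return raw, J


def run_swarm(
    swarm,
    objective,
    params: GSOParameters | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    on_step=None,
):
    """Run the GSO loop on one swarm's population, in place.

    ``objective`` maps a pose to either a float or a
    :class:`~glowdock.scoring.ScoreBreakdown` (the biased objective drives
    luciferin; the raw score is what agents record). Returns the swarm and
    the per-step best raw score trace. ``on_step(step, swarm)`` is an
    optional observer hook (used for snapshot writing).
    """
    params = params or GSOParameters()
    if rng is None:
        rng = np.random.default_rng(seed)
    population: list[Glowworm] = swarm.glowworms
    trace: list[float] = []
    for step in range(params.steps):
        for agent in population:
            agent.score, J = _evaluate(objective, agent.pose)
            agent.luciferin = luciferin_update(agent.luciferin, J, params)
        # synchronous movement from a snapshot of the post-update state
        snapshot = [agent.copy() for agent in population]
        new_poses: list[Pose] = []
        neighbor_counts: list[int] = []
        for agent, frozen in zip(population, snapshot):
            neighbors = find_neighbors(frozen, snapshot)
            neighbor_counts.append(len(neighbors))
            if neighbors:
                target = select_target(frozen, neighbors, rng)
                new_poses.append(move_glowworm(frozen, target, params))
            else:
                new_poses.append(frozen.pose)
        for agent, pose, n in zip(population, new_poses, neighbor_counts):
            agent.pose = pose
            agent.vision_range = update_vision_range(agent.vision_range, n, params)
        trace.append(max(agent.score for agent in population))
        if on_step is not None:
            on_step(step, swarm)
    # rescore so recorded scores match final poses
    for agent in population:
        agent.score, _ = _evaluate(objective, agent.pose)
    return swarm, trace
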