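"""Particle dynamics for standard and hierarchical heterogeneous PSO.

Standard particle swarm optimization (PSO) moves a population of candidate
solutions ("particles") through the unit hypercube, each attracted to its own
best position so far and to the best position any particle has found.  The
hierarchical heterogeneous variant (HHPSO) additionally ranks the swarm by
fitness into equally sized layers each iteration; every particle is pulled
toward a set of *attractors* — better-ranked peers — and switches its search
behavior when it detects premature convergence (stagnation of its personal
best, or crowding onto an attractor).

All updates are vectorized over coordinates.  Fitness is minimized
throughout.  Randomness comes from a single :class:`numpy.random.Generator`
per swarm, so a fixed seed yields a bit-identical trajectory.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Behavior",
    "Particle",
    "SwarmConfig",
    "Swarm",
    "acceleration_schedule",
    "inertia_weight",
    "pso_velocity_update",
    "hhpso_velocity_update",
    "position_update",
    "build_hierarchy",
    "attractors_of",
    "adapt_behavior",
]


class Behavior(enum.IntEnum):
    """Search behaviors a particle may adopt.

    ``FULL``
        the complete velocity update (previous velocity, global-best pull,
        personal-best pull, attractor pulls).
    ``COGNITIVE_ONLY``
        drop the global-best pull; the particle follows its own memory.
    ``SOCIAL_ONLY``
        drop the personal-best pull; the particle follows the swarm.
    ``REINIT``
        re-draw position and velocity uniformly at random each step
        (a restart / random-search behavior).
    """

    FULL = 0
    COGNITIVE_ONLY = 1
    SOCIAL_ONLY = 2
    REINIT = 3


@dataclass
class SwarmConfig:
    """Configuration of a swarm run.

    Parameters
    ----------
    n : population size (must be divisible by ``layers``).
    layers : number of hierarchy layers ``l``; each holds ``k = n / l``
        particles.
    omega_max, omega_min : inertia weight endpoints; ω decreases linearly
        from ``omega_max`` to ``omega_min`` over ``n_t`` iterations.
    c1_max, c1_min : global-best acceleration endpoints; c1 decreases
        linearly from ``c1_max`` to ``c1_min``.
    c2_min, c2_max : personal-best acceleration endpoints; c2 increases
        linearly from ``c2_min`` to ``c2_max``.
    c3 : constant attractor acceleration coefficient.
    n_t : hard iteration cap.
    vmax : per-coordinate velocity bound on the [0, 1] position range.
    theta : feature-selection threshold applied to position strings.
    patience : terminate once the global best position has not changed for
        this many consecutive iterations.
    stagnation_limit : personal-best stall length that triggers a behavior
        switch.
    crowding_epsilon : a particle closer than ``crowding_epsilon * sqrt(N)``
        to its nearest attractor is considered overcrowded.
    seed : seed for the swarm's random generator.
    """

    n: int = 50
    layers: int = 5
    omega_max: float = 0.9
    omega_min: float = 0.4
    c1_max: float = 2.5
    c1_min: float = 0.5
    c2_min: float = 0.5
    c2_max: float = 2.5
    c3: float = 0.5
    n_t: int = 500
    vmax: float = 0.2
    theta: float = 0.95
    patience: int = 50
    stagnation_limit: int = 10
    crowding_epsilon: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0 or self.layers <= 0 or self.n % self.layers != 0:
            raise ValueError(
                f"population size n={self.n} must be a positive multiple of "
                f"layers={self.layers}"
            )
        if not (0.0 < self.theta < 1.0):
            raise ValueError(f"theta must lie in (0, 1), got {self.theta}")
        if self.patience < 1:
            raise ValueError(f"patience must be >= 1, got {self.patience}")
        if self.n_t <= 0:
            raise ValueError(f"n_t must be positive, got {self.n_t}")
        if self.vmax <= 0:
            raise ValueError(f"vmax must be positive, got {self.vmax}")

    @property
    def layer_size(self) -> int:
        return self.n // self.layers

    def with_seed(self, seed: int) -> "SwarmConfig":
        return replace(self, seed=int(seed))


@dataclass
class Particle:
    """Snapshot of one particle's state (a view onto the swarm arrays)."""

    index: int
    position: np.ndarray
    velocity: np.ndarray
    personal_best_position: np.ndarray
    personal_best_fitness: float
    current_fitness: float
    stagnation_counter: int
    behavior: Behavior


def acceleration_schedule(t: int, cfg: SwarmConfig) -> tuple[float, float]:
    """Linear acceleration-coefficient schedules.

    c1 (global-best pull) decreases linearly from ``c1_max`` to ``c1_min``;
    c2 (personal-best pull) increases linearly from ``c2_min`` to ``c2_max``::

        c1(t) = (c1_min - c1_max) * t / n_t + c1_max
        c2(t) = (c2_max - c2_min) * t / n_t + c2_min
    """
    if cfg.n_t <= 0:
        raise ValueError("n_t must be positive")
    if not (0 <= t <= cfg.n_t):
        raise ValueError(f"iteration t={t} outside [0, {cfg.n_t}]")
    frac = t / cfg.n_t
    c1 = (cfg.c1_min - cfg.c1_max) * frac + cfg.c1_max
    c2 = (cfg.c2_max - cfg.c2_min) * frac + cfg.c2_min
    return c1, c2


def inertia_weight(t: int, cfg: SwarmConfig) -> float:
    """Inertia ω decreasing linearly from ``omega_max`` to ``omega_min``."""
    return cfg.omega_max + (cfg.omega_min - cfg.omega_max) * t / cfg.n_t


def _base_velocity(
    velocity: np.ndarray,
    position: np.ndarray,
    personal_best: np.ndarray,
    global_best: np.ndarray,
    omega: float,
    c1: float,
    c2: float,
    rng: np.random.Generator,
    include_global: bool = True,
    include_personal: bool = True,
) -> np.ndarray:
    # r1/r2 are always drawn so that behavior variants consume the random
    # stream identically (determinism of the trajectory across behaviors).
    n = position.shape[0]
    r1 = rng.random(n)
    r2 = rng.random(n)
    g = 1.0 if include_global else 0.0
    p = 1.0 if include_personal else 0.0
    return (
        omega * velocity
        + g * c1 * r1 * (global_best - position)
        + p * c2 * r2 * (personal_best - position)
    )


def pso_velocity_update(
    velocity: np.ndarray,
    position: np.ndarray,
    personal_best: np.ndarray,
    global_best: np.ndarray,
    omega: float,
    c1: float,
    c2: float,
    vmax: float,
    rng: np.random.Generator,
    include_global: bool = True,
    include_personal: bool = True,
) -> np.ndarray:
    """Standard PSO velocity update, clamped to ``[-vmax, vmax]``.

    Per coordinate j::

        V' = ω·V + c1·r1·(ŷ_j − x_j) + c2·r2·(y_j − x_j)

    where ŷ is the global best and y the personal best position, and r1, r2
    are uniform [0, 1) draws made per coordinate.
    """
    for other in (position, personal_best, global_best):
        if other.shape != velocity.shape:
            raise ValueError(
                f"dimension mismatch: {other.shape} vs {velocity.shape}"
            )
    v = _base_velocity(
        velocity, position, personal_best, global_best, omega, c1, c2, rng,
        include_global=include_global, include_personal=include_personal,
    )
    return np.clip(v, -vmax, vmax)


def hhpso_velocity_update(
    velocity: np.ndarray,
    position: np.ndarray,
    personal_best: np.ndarray,
    global_best: np.ndarray,
    attractor_positions: np.ndarray,
    omega: float,
    c1: float,
    c2: float,
    c3: float,
    vmax: float,
    rng: np.random.Generator,
    include_global: bool = True,
    include_personal: bool = True,
) -> np.ndarray:
    """HHPSO velocity update: the standard terms plus attractor pulls.

    ``attractor_positions`` is an (A, N) array; each attractor contributes
    ``c3·r3·(x_a − x)`` with r3 drawn per coordinate per attractor.  With an
    empty attractor set this reduces exactly to the standard update under
    the same random draws.
    """
    for other in (position, personal_best, global_best):
        if other.shape != velocity.shape:
            raise ValueError(
                f"dimension mismatch: {other.shape} vs {velocity.shape}"
            )
    v = _base_velocity(
        velocity, position, personal_best, global_best, omega, c1, c2, rng,
        include_global=include_global, include_personal=include_personal,
    )
    attractor_positions = np.atleast_2d(np.asarray(attractor_positions, dtype=float))
    if attractor_positions.size:
        if attractor_positions.shape[1] != position.shape[0]:
            raise ValueError("attractor dimension mismatch")
        for a in range(attractor_positions.shape[0]):
            r3 = rng.random(position.shape[0])
            v = v + c3 * r3 * (attractor_positions[a] - position)
    return np.clip(v, -vmax, vmax)


def position_update(position: np.ndarray, new_velocity: np.ndarray) -> np.ndarray:
    """Move by the (already clamped) velocity; clamp coordinates to [0, 1]."""
    return np.clip(position + new_velocity, 0.0, 1.0)


def build_hierarchy(fitness: np.ndarray, n_layers: int) -> np.ndarray:
    """Rank particles ascending by fitness into equally sized layers.

    Returns an ``(l, k)`` integer array of particle ids: row 0 is the top
    layer (best fitness).  Ties are broken by lower particle index (stable
    sort), making hierarchies deterministic.
    """
    fitness = np.asarray(fitness, dtype=float)
    n = fitness.shape[0]
    if n_layers <= 0 or n % n_layers != 0:
        raise ValueError(
            f"population {n} not divisible into {n_layers} equal layers"
        )
    order = np.argsort(fitness, kind="stable")
    return order.reshape(n_layers, n // n_layers)


def attractors_of(
    layers: np.ndarray, fitness: np.ndarray, particle_id: int
) -> np.ndarray:
    """Ids of the attractors of one particle under the current hierarchy.

    Top-layer particles are attracted to same-layer peers with strictly
    better (lower) fitness; every other particle is attracted to all
    particles of its immediately superior layer.
    """
    fitness = np.asarray(fitness, dtype=float)
    layers = np.asarray(layers)
    where = np.argwhere(layers == particle_id)
    if where.size == 0:
        raise KeyError(f"unknown particle id {particle_id}")
    layer_idx = int(where[0, 0])
    if layer_idx == 0:
        peers = layers[0]
        return peers[fitness[peers] < fitness[particle_id]]
    return layers[layer_idx - 1].copy()


def adapt_behavior(
    current: Behavior,
    stagnation_counter: int,
    position: np.ndarray,
    attractor_positions: np.ndarray,
    cfg: SwarmConfig,
    rng: np.random.Generator,
) -> tuple[Behavior, int]:
    """Switch behavior on a premature-convergence signal.

    Triggers on early stagnation (personal best unimproved for
    ``stagnation_limit`` iterations) or overcrowding (Euclidean distance to
    the nearest attractor below ``crowding_epsilon * sqrt(N)``).  On trigger
    a new behavior is drawn uniformly from the pool excluding the current
    one and the stagnation counter resets; otherwise state is unchanged.
    """
    trigger = stagnation_counter >= cfg.stagnation_limit
    attractor_positions = np.atleast_2d(np.asarray(attractor_positions, dtype=float))
    if not trigger and attractor_positions.size:
        dists = np.linalg.norm(attractor_positions - position, axis=1)
        trigger = bool(dists.min() < cfg.crowding_epsilon * np.sqrt(position.shape[0]))
    if not trigger:
        return current, stagnation_counter
    pool = [b for b in Behavior if b != current]
    new = pool[int(rng.integers(len(pool)))]
    return new, 0


class Swarm:
    """Mutable swarm state driving either the standard or hierarchical
    update rule.

    The owner calls :meth:`evaluate` with the current fitness of every
    particle, then :meth:`rank`, then :meth:`move`; one such round is one
    iteration.  ``hierarchical=False`` gives plain PSO (no layers, no
    attractors, no behavior adaptation).
    """

    def __init__(
        self,
        n_features: int,
        cfg: SwarmConfig,
        rng: np.random.Generator | None = None,
        hierarchical: bool = True,
    ) -> None:
        self.cfg = cfg
        self.n_features = int(n_features)
        self.hierarchical = hierarchical
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        n = cfg.n
        self.positions = self.rng.random((n, n_features))
        self.velocities = self.rng.uniform(-0.1, 0.1, (n, n_features))
        self.personal_best_positions = self.positions.copy()
        self.personal_best_fitness = np.full(n, np.inf)
        self.current_fitness = np.full(n, np.inf)
        self.stagnation = np.zeros(n, dtype=int)
        self.behaviors = np.full(n, int(Behavior.FULL), dtype=int)
        self.global_best_position: np.ndarray | None = None
        self.global_best_fitness: float = np.inf
        self.layers: np.ndarray | None = None
        self.iteration = 0

    def particle(self, i: int) -> Particle:
        return Particle(
            index=i,
            position=self.positions[i].copy(),
            velocity=self.velocities[i].copy(),
            personal_best_position=self.personal_best_positions[i].copy(),
            personal_best_fitness=float(self.personal_best_fitness[i]),
            current_fitness=float(self.current_fitness[i]),
            stagnation_counter=int(self.stagnation[i]),
            behavior=Behavior(self.behaviors[i]),
        )

    def evaluate(self, fitness: np.ndarray) -> None:
        """Record this iteration's fitness; update personal and global bests.

        A personal best updates only on strict improvement; the stagnation
        counter resets on improvement and increments otherwise.
        """
        fitness = np.asarray(fitness, dtype=float)
        if fitness.shape != (self.cfg.n,):
            raise ValueError("one fitness value per particle required")
        self.current_fitness = fitness.copy()
        improved = fitness < self.personal_best_fitness
        self.personal_best_fitness[improved] = fitness[improved]
        self.personal_best_positions[improved] = self.positions[improved]
        self.stagnation[improved] = 0
        self.stagnation[~improved] += 1
        best = int(np.argmin(self.personal_best_fitness))
        # strict improvement keeps the global best position stable under
        # ties; an all-sentinel swarm still anchors on the first minimizer
        if self.global_best_position is None or \
                self.personal_best_fitness[best] < self.global_best_fitness:
            self.global_best_fitness = float(self.personal_best_fitness[best])
            self.global_best_position = self.personal_best_positions[best].copy()

    def rank(self) -> None:
        """Rebuild the hierarchy from the current fitness values."""
        if self.hierarchical:
            self.layers = build_hierarchy(self.current_fitness, self.cfg.layers)

    def move(self, t: int | None = None) -> None:
        """One velocity/position update of every particle (index order)."""
        if t is None:
            t = self.iteration
        cfg = self.cfg
        omega = inertia_weight(t, cfg)
        c1, c2 = acceleration_schedule(t, cfg)
        gbest = self.global_best_position
        if gbest is None:
            raise RuntimeError("evaluate() must run before move()")
        snapshot = self.positions.copy()  # attractor pulls use start-of-step positions
        for i in range(cfg.n):
            if not self.hierarchical:
                v = pso_velocity_update(
                    self.velocities[i], self.positions[i],
                    self.personal_best_positions[i], gbest,
                    omega, c1, c2, cfg.vmax, self.rng,
                )
                self.velocities[i] = v
                self.positions[i] = position_update(self.positions[i], v)
                continue
            if self.layers is None:
                raise RuntimeError("rank() must run before move() for HHPSO")
            attr_ids = attractors_of(self.layers, self.current_fitness, i)
            attr_pos = snapshot[attr_ids] if attr_ids.size else np.empty((0, self.n_features))
            behavior, counter = adapt_behavior(
                Behavior(self.behaviors[i]), int(self.stagnation[i]),
                self.positions[i], attr_pos, cfg, self.rng,
            )
            self.behaviors[i] = int(behavior)
            self.stagnation[i] = counter
            if behavior is Behavior.REINIT:
                self.positions[i] = self.rng.random(self.n_features)
                self.velocities[i] = self.rng.uniform(-0.1, 0.1, self.n_features)
                continue
            v = hhpso_velocity_update(
                self.velocities[i], self.positions[i],
                self.personal_best_positions[i], gbest, attr_pos,
                omega, c1, c2, cfg.c3, cfg.vmax, self.rng,
                include_global=behavior is not Behavior.COGNITIVE_ONLY,
                include_personal=behavior is not Behavior.SOCIAL_ONLY,
            )
            self.velocities[i] = v
            self.positions[i] = position_update(self.positions[i], v)
        self.iteration = t + 1
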