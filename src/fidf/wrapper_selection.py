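"""Wrapper feature selection: swarm optimizers and greedy/no-selection
baselines around a linear-SVM error evaluator.

A particle's position string in [0, 1]^N encodes per-feature importance; a
threshold θ (default 0.95, strict inequality) converts it to a feature
subset.  Candidate subsets are scored by the fitness

    f(S) = Error(S) / (N - |S|)

which is minimized: it rewards both low cross-validated classification
error and small subsets (more eliminated features inflate the denominator).
Empty and full subsets receive a sentinel worst fitness — the ratio is
undefined at |S| = N and no classifier can be fit at |S| = 0.

The evaluator passed to every selector is a callable mapping a tuple of
feature indices to a cross-validated error rate (see
:class:`fidf.model_eval.InnerCVEvaluator`); it must be deterministic for a
fixed subset within one run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_eval import FeatureMatrix
from .swarm_core import Swarm, SwarmConfig

__all__ = [
    "WORST_FITNESS",
    "FeatureSubset",
    "FitnessRecord",
    "SelectionRun",
    "threshold_select",
    "fitness_value",
    "hhpso_svm_select",
    "pso_svm_select",
    "greedy_sequential_select",
    "wfs_evaluate",
    "wfs_select",
    "SELECTORS",
]

WORST_FITNESS = math.inf


@dataclass(frozen=True)
class FeatureSubset:
    """A sorted, duplicate-free set of selected feature indices."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(j) for j in self.indices))
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate feature indices")
        if idx and idx[0] < 0:
            raise ValueError("negative feature index")
        object.__setattr__(self, "indices", idx)

    @property
    def size(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


@dataclass
class FitnessRecord:
    subset: FeatureSubset
    error: float
    fitness: float
    n_total: int

    @property
    def accuracy(self) -> float:
        return 1.0 - self.error


@dataclass
class SelectionRun:
    """Outcome of one selection run.

    ``history`` holds one ``(global_best_fitness, global_best_subset_size)``
    pair per iteration; the fitness sequence is non-increasing.
    ``best_position`` is the final global-best position string (for greedy
    and no-selection baselines, a 0/1 indicator of the final subset).
    """

    final_subset: FeatureSubset
    best_fitness: float
    best_position: np.ndarray
    iterations_used: int
    history: list[tuple[float, int]]
    seed: int


def threshold_select(position: np.ndarray, theta: float) -> FeatureSubset:
    """Features whose position value strictly exceeds θ."""
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    position = np.asarray(position, dtype=float)
    return FeatureSubset(tuple(int(j) for j in np.flatnonzero(position > theta)))


def fitness_value(error: float, subset_size: int, n_total: int) -> float:
    """Error over the number of eliminated features; minimized.

    Degenerate subsets (empty, or the full feature set where the
    denominator vanishes) receive the sentinel worst fitness.
    """
    if not (0.0 <= error <= 1.0):
        raise ValueError(f"error must lie in [0, 1], got {error}")
    if not (0 <= subset_size <= n_total):
        raise ValueError("subset size out of range")
    if subset_size == 0 or subset_size == n_total:
        return WORST_FITNESS
    return error / (n_total - subset_size)


class _MemoizedFitness:
    """Per-run fitness cache keyed by the subset's index tuple."""

    def __init__(self, evaluator, n_total: int):
        self.evaluator = evaluator
        self.n_total = n_total
        self._cache: dict[tuple[int, ...], float] = {}

    def __call__(self, subset: FeatureSubset) -> float:
        key = subset.indices
        if key in self._cache:
            return self._cache[key]
        if subset.size == 0 or subset.size == self.n_total:
            fit = WORST_FITNESS
        else:
            fit = fitness_value(float(self.evaluator(key)), subset.size, self.n_total)
        self._cache[key] = fit
        return fit


def _check_data(data: FeatureMatrix) -> None:
    if data.n_instances == 0 or data.n_features == 0:
        raise ValueError("empty feature matrix")
    if np.unique(data.labels).size < 2:
        raise ValueError("selection requires at least two classes")


def _swarm_select(
    data: FeatureMatrix,
    cfg: SwarmConfig,
    evaluator,
    hierarchical: bool,
) -> SelectionRun:
    _check_data(data)
    n_features = data.n_features
    fitness_of = _MemoizedFitness(evaluator, n_features)
    swarm = Swarm(n_features, cfg, hierarchical=hierarchical)
    history: list[tuple[float, int]] = []
    prev_best: np.ndarray | None = None
    stall = 0
    iterations = 0
    for t in range(cfg.n_t):
        fits = np.array([
            fitness_of(threshold_select(swarm.positions[i], cfg.theta))
            for i in range(cfg.n)
        ])
        swarm.evaluate(fits)
        iterations = t + 1
        gbest = swarm.global_best_position
        assert gbest is not None
        history.append(
            (swarm.global_best_fitness, threshold_select(gbest, cfg.theta).size)
        )
        if prev_best is not None and np.array_equal(gbest, prev_best):
            stall += 1
        else:
            stall = 0
        prev_best = gbest.copy()
        if stall >= cfg.patience:
            break
        swarm.rank()
        swarm.move(t)
    final_position = swarm.global_best_position
    assert final_position is not None
    final_subset = threshold_select(final_position, cfg.theta)
    return SelectionRun(
        final_subset=final_subset,
        best_fitness=float(swarm.global_best_fitness),
        best_position=final_position.copy(),
        iterations_used=iterations,
        history=history,
        seed=cfg.seed,
    )


def hhpso_svm_select(data: FeatureMatrix, cfg: SwarmConfig, evaluator) -> SelectionRun:
    """Hierarchical heterogeneous PSO wrapper selection.

    Each iteration: (1) threshold every position, evaluate fitness, update
    personal/global bests; (2) rank the swarm ascending by fitness into
    layers; (3) behavior-aware velocity/position updates with attractor
    pulls.  Terminates when the global best position has not changed for
    ``cfg.patience`` consecutive iterations, or at the ``cfg.n_t`` cap.
    """
    return _swarm_select(data, cfg, evaluator, hierarchical=True)


def pso_svm_select(data: FeatureMatrix, cfg: SwarmConfig, evaluator) -> SelectionRun:
    """Standard PSO wrapper selection: same objective, threshold and
    termination as the hierarchical variant, but the plain velocity update
    (no layers, no attractors, no behavior adaptation)."""
    return _swarm_select(data, cfg, evaluator, hierarchical=False)


def _indicator(indices, n_features: int) -> np.ndarray:
    v = np.zeros(n_features)
    v[list(indices)] = 1.0
    return v


def greedy_sequential_select(
    data: FeatureMatrix,
    direction: str,
    evaluator,
    cfg: SwarmConfig | None = None,
) -> SelectionRun:
    """Sequential forward ('forward'/'sfs') or backward ('backward'/'sbs')
    selection under the same fitness as the swarm methods.

    At each step the single add (forward) or drop (backward) that most
    improves fitness is applied; ties break to the lowest feature index;
    the search stops when no single change improves.  Deterministic.
    """
    _check_data(data)
    direction = direction.lower()
    if direction in ("forward", "sfs"):
        forward = True
    elif direction in ("backward", "sbs"):
        forward = False
    else:
        raise ValueError(f"unknown direction {direction!r}")
    n_features = data.n_features
    fitness_of = _MemoizedFitness(evaluator, n_features)
    current: set[int] = set() if forward else set(range(n_features))
    current_fit = WORST_FITNESS
    history: list[tuple[float, int]] = []
    while True:
        best_j: int | None = None
        best_fit = current_fit
        candidates = sorted(set(range(n_features)) - current if forward else current)
        for j in candidates:
            trial = current | {j} if forward else current - {j}
            fit = fitness_of(FeatureSubset(tuple(trial)))
            if fit < best_fit:  # strict: first (lowest-index) winner kept
                best_fit = fit
                best_j = j
        if best_j is None:
            break
        current = current | {best_j} if forward else current - {best_j}
        current_fit = best_fit
        history.append((current_fit, len(current)))
    subset = FeatureSubset(tuple(current))
    return SelectionRun(
        final_subset=subset,
        best_fitness=current_fit,
        best_position=_indicator(subset.indices, n_features),
        iterations_used=len(history),
        history=history,
        seed=cfg.seed if cfg is not None else 0,
    )


def wfs_evaluate(data: FeatureMatrix, evaluator) -> FitnessRecord:
    """No-selection baseline: classifier error on the full feature set.

    The ratio fitness is undefined at the full set, so the record carries
    the sentinel worst fitness; the error/accuracy fields are the
    quantities of interest.
    """
    _check_data(data)
    full = FeatureSubset(tuple(range(data.n_features)))
    error = float(evaluator(full.indices))
    return FitnessRecord(
        subset=full,
        error=error,
        fitness=fitness_value(error, full.size, data.n_features),
        n_total=data.n_features,
    )


def wfs_select(data: FeatureMatrix, cfg: SwarmConfig, evaluator) -> SelectionRun:
    """Adapter presenting the no-selection baseline as a SelectionRun
    (final subset = all features), so it can drive the two-stage pipeline."""
    record = wfs_evaluate(data, evaluator)
    return SelectionRun(
        final_subset=record.subset,
        best_fitness=record.fitness,
        best_position=np.ones(data.n_features),
        iterations_used=1,
        history=[(record.fitness, record.subset.size)],
        seed=cfg.seed if cfg is not None else 0,
    )


def _sfs(data, cfg, evaluator):
    return greedy_sequential_select(data, "forward", evaluator, cfg)


def _sbs(data, cfg, evaluator):
    return greedy_sequential_select(data, "backward", evaluator, cfg)


#: Selection methods by name, all sharing the (data, cfg, evaluator) signature.
SELECTORS = {
    "hhpso": hhpso_svm_select,
    "pso": pso_svm_select,
    "sfs": _sfs,
    "sbs": _sbs,
    "wfs": wfs_select,
}
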