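"""The two-stage feature interaction detection pipeline.

Stage I runs a wrapper feature selector repeatedly (15 times by default) on
the training portions, ranks features by how often they were selected, and
keeps the top N1 = ceil(1.05 * N_avg), where N_avg is the mean selected
subset size.  Stage II forms one column per unordered pair of the Stage-I
features — the element-wise product of the two (z-scored) feature columns,
a proxy for the functional coupling of two voxels — and applies the same
selection-and-ranking mechanism to the N1(N1-1)/2 product columns.  The
held-out portion of the current outer fold is never seen by either stage;
it only scores the final feature sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .glm_features import apply_zscore, zscore_standardize
from .model_eval import FeatureMatrix, InnerCVEvaluator, train_and_error
from .swarm_core import SwarmConfig
from .wrapper_selection import SELECTORS, SelectionRun

__all__ = [
    "SelectionOutcome",
    "ConnectivityFeatureSet",
    "FoldResult",
    "FidfResult",
    "default_evaluator_factory",
    "repeat_and_rank",
    "build_connectivity_features",
    "run_stage1",
    "run_stage2",
    "fidf_fold",
    "run_fidf",
]


@dataclass
class SelectionOutcome:
    """Aggregate of repeated selection runs over one feature space.

    ``frequency[j]`` counts the runs whose final subset contains feature j;
    ``n_avg`` is the mean final-subset size, ``n1 = ceil(1.05 * n_avg)``
    (capped at the feature count), and ``selected`` holds the top-``n1``
    features ranked by descending frequency (ties: descending mean
    global-best position value, then lowest index).
    """

    runs: list[SelectionRun]
    frequency: np.ndarray
    n_avg: float
    n1: int
    selected: np.ndarray

    @property
    def stage1_features(self) -> np.ndarray:  # alias used by Stage-I callers
        return self.selected


@dataclass
class ConnectivityFeatureSet:
    """Pairwise-product (connectivity) columns over a base feature set.

    ``pairs`` lists the unordered index pairs (j, k), j < k, in
    lexicographic order; column i of ``columns`` holds the per-instance
    product of base features ``pairs[i]``.
    """

    pairs: list[tuple[int, int]]
    columns: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def default_evaluator_factory(inner_repeats: int = 20):
    """Factory building the portion-split inner-CV evaluator for a run.

    The 6-train/5-test split of the default 11-portion pool generalizes
    proportionally to other portion counts (e.g. 6/4 on 10 portions).
    """

    def make(data: FeatureMatrix, seed: int) -> InnerCVEvaluator:
        n_portions = data.portion_ids().size
        n_train = max(1, min(n_portions - 1, round(n_portions * 6 / 11)))
        return InnerCVEvaluator(
            data,
            repeats=inner_repeats,
            rng=np.random.default_rng(seed),
            n_train_portions=n_train,
            n_test_portions=n_portions - n_train,
        )

    return make


def _resolve_method(method):
    if callable(method):
        return method
    try:
        return SELECTORS[str(method).lower()]
    except KeyError:
        raise ValueError(
            f"unknown selection method {method!r}; choose from {sorted(SELECTORS)}"
        ) from None


def repeat_and_rank(
    data: FeatureMatrix,
    method,
    cfg: SwarmConfig,
    repeats: int = 15,
    seed: int = 0,
    evaluator_factory=None,
) -> SelectionOutcome:
    """Run the selector ``repeats`` times and rank features by selection
    frequency.

    Run r uses swarm seed ``seed + r`` and a fresh inner-CV split drawn
    from a distinct stream, so the repeats are independent replicates.
    Empty final subsets count as size 0.  ``n1`` is capped at the number
    of features.
    """
    select = _resolve_method(method)
    if evaluator_factory is None:
        evaluator_factory = default_evaluator_factory()
    n_features = data.n_features
    runs: list[SelectionRun] = []
    frequency = np.zeros(n_features, dtype=int)
    position_sum = np.zeros(n_features)
    sizes = []
    for r in range(repeats):
        run_cfg = cfg.with_seed(seed + r)
        evaluator = evaluator_factory(data, seed + 90019 + r)
        run = select(data, run_cfg, evaluator)
        runs.append(run)
        idx = run.final_subset.as_array()
        if idx.size:
            frequency[idx] += 1
        position_sum += run.best_position
        sizes.append(run.final_subset.size)
    n_avg = float(np.mean(sizes)) if sizes else 0.0
    n1 = min(int(math.ceil(1.05 * n_avg)), n_features)
    mean_position = position_sum / max(len(runs), 1)
    # primary: frequency desc; then mean position desc; then index asc
    order = np.lexsort((np.arange(n_features), -mean_position, -frequency))
    selected = np.sort(order[:n1])
    return SelectionOutcome(
        runs=runs,
        frequency=frequency,
        n_avg=n_avg,
        n1=n1,
        selected=selected,
    )


def build_connectivity_features(
    values: np.ndarray, stage1_features
) -> ConnectivityFeatureSet:
    """One product column per unordered pair of Stage-I features.

    Pair order is lexicographic in (j, k) with j < k, giving exactly
    n1(n1-1)/2 columns.
    """
    base = sorted(int(j) for j in np.asarray(stage1_features).ravel())
    if len(base) < 2:
        raise ValueError("connectivity needs at least two base features")
    values = np.asarray(values, dtype=float)
    pairs = list(combinations(base, 2))
    columns = np.column_stack([values[:, j] * values[:, k] for j, k in pairs])
    return ConnectivityFeatureSet(pairs=pairs, columns=columns)


def run_stage1(
    data: FeatureMatrix,
    method,
    cfg: SwarmConfig,
    repeats: int = 15,
    seed: int = 0,
    evaluator_factory=None,
) -> SelectionOutcome:
    """Stage I: repeated voxel selection on the training portions."""
    data.validate()
    return repeat_and_rank(
        data, method, cfg, repeats=repeats, seed=seed,
        evaluator_factory=evaluator_factory,
    )


def run_stage2(
    data: FeatureMatrix,
    stage1: SelectionOutcome,
    method,
    cfg: SwarmConfig,
    repeats: int = 15,
    seed: int = 0,
    evaluator_factory=None,
) -> tuple[ConnectivityFeatureSet, SelectionOutcome]:
    """Stage II: the same selection mechanism on pairwise-product columns.

    The product columns are re-standardized (z-score over the training
    rows) before selection; threshold, objective and aggregation are
    identical to Stage I.
    """
    conn = build_connectivity_features(data.values, stage1.selected)
    z, _, _ = zscore_standardize(conn.columns)
    conn_data = FeatureMatrix(z, data.labels, data.portions)
    outcome = repeat_and_rank(
        conn_data, method, cfg, repeats=repeats, seed=seed,
        evaluator_factory=evaluator_factory,
    )
    return conn, outcome


def _holdout_accuracy(train_x, train_y, test_x, test_y, n_classes: int) -> float:
    if train_x.shape[1] == 0:
        return 1.0 / n_classes  # no features selected: chance-level prediction
    return 1.0 - train_and_error(train_x, train_y, test_x, test_y)


@dataclass
class FoldResult:
    """Everything one outer fold produced."""

    portion: object
    stage1: SelectionOutcome
    stage2: SelectionOutcome
    connectivity_pairs: list[tuple[int, int]]
    selected_pairs: list[tuple[int, int]]
    stage1_accuracy: float
    stage2_accuracy: float


@dataclass
class FidfResult:
    """Per-fold results plus the two accuracy summaries."""

    folds: list[FoldResult]

    def stage1_accuracies(self) -> np.ndarray:
        return np.array([f.stage1_accuracy for f in self.folds])

    def stage2_accuracies(self) -> np.ndarray:
        return np.array([f.stage2_accuracy for f in self.folds])


def fidf_fold(
    train: FeatureMatrix,
    holdout: FeatureMatrix,
    method,
    cfg: SwarmConfig,
    repeats: int = 15,
    seed: int = 0,
    evaluator_factory=None,
    stage1_override: np.ndarray | None = None,
) -> FoldResult:
    """Run both stages on one outer fold and score the holdout.

    Standardization statistics (for the raw features and again for the
    product columns) are fit on the training rows only and applied to the
    holdout, which neither stage ever sees.  ``stage1_override`` skips the
    Stage-I search and treats the given indices as the Stage-I set.
    """
    z_train, mean, sd = zscore_standardize(train.values)
    z_hold = apply_zscore(holdout.values, mean, sd)
    train_z = train.with_values(z_train)
    n_classes = train.n_classes

    if stage1_override is not None:
        stage1 = SelectionOutcome(
            runs=[],
            frequency=np.zeros(train.n_features, dtype=int),
            n_avg=float(len(stage1_override)),
            n1=len(stage1_override),
            selected=np.sort(np.asarray(stage1_override, dtype=int)),
        )
    else:
        stage1 = run_stage1(
            train_z, method, cfg, repeats=repeats, seed=seed,
            evaluator_factory=evaluator_factory,
        )
    s1 = stage1.selected
    stage1_acc = _holdout_accuracy(
        z_train[:, s1], train.labels, z_hold[:, s1], holdout.labels, n_classes
    )

    conn_train, stage2 = run_stage2(
        train_z, stage1, method, cfg, repeats=repeats, seed=seed + 31337,
        evaluator_factory=evaluator_factory,
    )
    _, pmean, psd = zscore_standardize(conn_train.columns)
    conn_hold = build_connectivity_features(z_hold, stage1.selected)
    hold_cols = apply_zscore(conn_hold.columns, pmean, psd)
    train_cols = apply_zscore(conn_train.columns, pmean, psd)
    s2 = stage2.selected
    stage2_acc = _holdout_accuracy(
        train_cols[:, s2], train.labels, hold_cols[:, s2], holdout.labels, n_classes
    )
    return FoldResult(
        portion=None,
        stage1=stage1,
        stage2=stage2,
        connectivity_pairs=conn_train.pairs,
        selected_pairs=[conn_train.pairs[i] for i in s2],
        stage1_accuracy=float(stage1_acc),
        stage2_accuracy=float(stage2_acc),
    )


def run_fidf(
    data: FeatureMatrix,
    method,
    cfg: SwarmConfig,
    repeats: int = 15,
    seed: int = 0,
    evaluator_factory=None,
    portions=None,
    stage1_override: np.ndarray | None = None,
) -> FidfResult:
    """The full nested protocol: hold out each portion once, run both
    stages on the rest, score the holdout.

    ``portions`` restricts evaluation to a subset of holdout portions
    (useful for scaled-down runs); the default is every portion, i.e. the
    12-fold protocol on 12-run data.
    """
    data.validate()
    if portions is None:
        portions = data.portion_ids()
    folds: list[FoldResult] = []
    for f_idx, portion in enumerate(portions):
        train, holdout = data.split_portion(portion)
        result = fidf_fold(
            train, holdout, method, cfg,
            repeats=repeats, seed=seed + 1009 * f_idx,
            evaluator_factory=evaluator_factory,
            stage1_override=stage1_override,
        )
        result.portion = portion
        folds.append(result)
    return FidfResult(folds=folds)
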