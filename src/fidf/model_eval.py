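"""Classifier contract and nested cross-validation.

The outer protocol splits the data into 12 portions (fMRI runs when run ids
are available).  Each portion is held out once; the whole selection pipeline
runs on the remaining 11, and holdout accuracy is recorded.  During
selection, fitness of a candidate feature subset is estimated by repeatedly
splitting the 11 training portions at random into 6 train / 5 test portions
(20 repeats by default) and averaging the linear-SVM test error.

The inner splits are drawn once per selection run and reused for every
subset evaluated in that run, so fitness values are directly comparable
across particles within a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

__all__ = [
    "FeatureMatrix",
    "CvReport",
    "train_and_error",
    "InnerCVEvaluator",
    "inner_cv_error",
    "outer_cv",
]


@dataclass
class FeatureMatrix:
    """An M x N matrix of real-valued features (GLM beta coefficients),
    one class label and one portion (run) id per row."""

    values: np.ndarray
    labels: np.ndarray
    portions: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.portions = np.asarray(self.portions)
        m, _ = self.values.shape
        if self.labels.shape != (m,) or self.portions.shape != (m,):
            raise ValueError("labels and portions must have one entry per row")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at row {bad[0]}, column {bad[1]}"
            )
    def validate(self, n_portions: int | None = None) -> "FeatureMatrix":
        """Check the full-protocol invariants: >=2 classes, every class
        present at least twice, and (optionally) an exact portion count.

        Row slices such as a single held-out run legitimately violate these,
        so the checks run at protocol entry points rather than on
        construction.
        """
        classes, counts = np.unique(self.labels, return_counts=True)
        if classes.size < 2:
            raise ValueError("at least two classes required")
        if counts.min() < 2:
            raise ValueError("every class must appear at least twice")
        if n_portions is not None and self.portion_ids().size != n_portions:
            raise ValueError(
                f"expected {n_portions} portions, found {self.portion_ids().size}"
            )
        return self

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.labels).size)

    def portion_ids(self) -> np.ndarray:
        return np.unique(self.portions)

    def restrict_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.values[mask], self.labels[mask], self.portions[mask])

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(values, self.labels.copy(), self.portions.copy())

    def split_portion(self, portion) -> tuple["FeatureMatrix", "FeatureMatrix"]:
        """(training pool without `portion`, holdout = `portion`)."""
        hold = self.portions == portion
        if not hold.any():
            raise KeyError(f"unknown portion {portion!r}")
        return self.restrict_rows(~hold), self.restrict_rows(hold)


@dataclass
class CvReport:
    """Per-fold holdout accuracies with their mean and sample SD."""

    fold_accuracies: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)
        self.mean = float(self.fold_accuracies.mean())
        self.sd = float(self.fold_accuracies.std(ddof=1)) if self.fold_accuracies.size > 1 else 0.0


def _classifier() -> LinearSVC:
    # Linear maximum-margin classifier, C=1, one-vs-rest for K>2.  The
    # primal solver is deterministic, so fitness evaluation is repeatable.
    return LinearSVC(C=1.0, dual=False)


def train_and_error(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    test_y: np.ndarray,
) -> float:
    """Fit the linear SVM on the training split; return the test
    misclassification fraction."""
    if np.unique(train_y).size < 2:
        raise ValueError("training split contains a single class")
    if train_x.ndim != 2 or train_x.shape[1] == 0:
        raise ValueError("training matrix must have at least one feature column")
    clf = _classifier()
    clf.fit(train_x, train_y)
    pred = clf.predict(test_x)
    return float(np.mean(pred != test_y))


class InnerCVEvaluator:
    """Subset-error estimator over random portion-level splits.

    Draws ``repeats`` random partitions of the training portions into
    ``n_train_portions`` train / ``n_test_portions`` test groups at
    construction time; calling the evaluator with a feature-index tuple
    returns the error averaged over those fixed splits.  Results are
    memoized per subset, so re-evaluating a subset costs one dictionary
    lookup.
    """

    def __init__(
        self,
        data: FeatureMatrix,
        repeats: int = 20,
        rng: np.random.Generator | int | None = None,
        n_train_portions: int = 6,
        n_test_portions: int = 5,
    ) -> None:
        if isinstance(rng, (int, np.integer)) or rng is None:
            rng = np.random.default_rng(rng)
        portions = data.portion_ids()
        if portions.size != n_train_portions + n_test_portions:
            raise ValueError(
                f"training pool has {portions.size} portions; expected "
                f"{n_train_portions + n_test_portions} "
                f"({n_train_portions} train + {n_test_portions} test)"
            )
        self.data = data
        self.repeats = int(repeats)
        self._splits: list[tuple[np.ndarray, np.ndarray]] = []
        for _ in range(self.repeats):
            perm = rng.permutation(portions)
            train_p = perm[:n_train_portions]
            train_mask = np.isin(data.portions, train_p)
            self._splits.append((train_mask, ~train_mask))
        self._cache: dict[tuple[int, ...], float] = {}
        self.n_evaluations = 0

    def __call__(self, subset) -> float:
        key = tuple(sorted(int(j) for j in subset))
        if not key:
            raise ValueError("cannot evaluate an empty feature subset")
        if key in self._cache:
            return self._cache[key]
        cols = np.asarray(key, dtype=int)
        errors = []
        for train_mask, test_mask in self._splits:
            errors.append(
                train_and_error(
                    self.data.values[np.ix_(train_mask, cols)],
                    self.data.labels[train_mask],
                    self.data.values[np.ix_(test_mask, cols)],
                    self.data.labels[test_mask],
                )
            )
        err = float(np.mean(errors))
        self._cache[key] = err
        self.n_evaluations += 1
        return err


def inner_cv_error(
    train_pool: FeatureMatrix,
    subset,
    repeats: int = 20,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mean linear-SVM error of `subset` over random 6/5 portion splits of
    an 11-portion training pool (the default inner protocol)."""
    return InnerCVEvaluator(train_pool, repeats=repeats, rng=rng)(subset)


def outer_cv(data: FeatureMatrix, pipeline, seed: int = 0) -> CvReport:
    """Hold out each portion once; run `pipeline` on the rest.

    `pipeline(train, holdout, fold_seed)` must return the holdout accuracy
    for that fold.  With run ids present the portions are the 12 runs, so
    this is the block-respecting 12-fold protocol.
    """
    portions = data.portion_ids()
    accuracies = []
    for fold, portion in enumerate(portions):
        train, holdout = data.split_portion(portion)
        try:
            acc = float(pipeline(train, holdout, int(seed) + fold))
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on fold {fold} (portion {portion!r})") from exc
        accuracies.append(acc)
    return CvReport(np.asarray(accuracies))
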