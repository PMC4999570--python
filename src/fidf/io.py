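"""Readers and writers for the pipeline's delimited-text formats.

Feature matrices travel as comma-separated text with '#'-prefixed metadata
lines, a header row, a ``label`` column, an optional ``portion`` column and
one column per feature.  Selection reports list per-feature selection
frequency, mean global-best position value and a selected flag, preceded by
a metadata block (n_avg, n1, seed, config hash).  Everything is
human-diffable and round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fidf_pipeline import SelectionOutcome
from .model_eval import FeatureMatrix
from .swarm_core import SwarmConfig

__all__ = [
    "RunConfig",
    "read_feature_matrix",
    "write_feature_matrix",
    "write_selection_report",
    "write_cv_report",
    "load_config",
    "config_hash",
]


@dataclass
class RunConfig:
    """Top-level run configuration: swarm settings plus protocol knobs."""

    swarm: SwarmConfig = dataclasses.field(default_factory=SwarmConfig)
    method: str = "hhpso"
    repeats: int = 15
    folds: int = 12
    inner_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1 or self.folds < 1 or self.inner_repeats < 1:
            raise ValueError("repeats, folds and inner_repeats must be >= 1")


def config_hash(cfg: RunConfig) -> str:
    """Short digest of the semantic fields (changes iff any field does)."""
    payload = {
        "swarm": dataclasses.asdict(cfg.swarm),
        "method": cfg.method,
        "repeats": cfg.repeats,
        "folds": cfg.folds,
        "inner_repeats": cfg.inner_repeats,
        "seed": cfg.seed,
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read a TOML config with optional [swarm] and [run] sections."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    swarm = SwarmConfig(**raw.get("swarm", {}))
    run = raw.get("run", {})
    return RunConfig(swarm=swarm, **run)


def write_feature_matrix(data: FeatureMatrix, path, metadata: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        cols = ["label", "portion"] + [f"f{j}" for j in range(data.n_features)]
        fh.write(",".join(cols) + "\n")
        for i in range(data.n_instances):
            row = [str(data.labels[i]), str(data.portions[i])]
            row += [repr(float(v)) for v in data.values[i]]
            fh.write(",".join(row) + "\n")


def read_feature_matrix(path, label_column: str = "label") -> FeatureMatrix:
    """Read a delimited feature matrix, validating shape and finiteness.

    Missing or non-numeric cells are rejected with their row and column
    location; an absent ``portion`` column yields a single portion 0.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed rows ({exc})") from exc
    if label_column not in frame.columns:
        raise ValueError(
            f"{path}: no label column {label_column!r}; columns are "
            f"{list(frame.columns)}"
        )
    labels = frame[label_column].to_numpy()
    if "portion" in frame.columns:
        portions = frame["portion"].to_numpy()
        feat = frame.drop(columns=[label_column, "portion"])
    else:
        portions = np.zeros(len(frame), dtype=int)
        feat = frame.drop(columns=[label_column])
    values = feat.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for col in feat.columns:
            if not np.issubdtype(feat[col].dtype, np.number):
                bad = int(feat[col].map(
                    lambda v: not isinstance(v, (int, float))
                ).idxmax())
                raise ValueError(
                    f"{path}: non-numeric cell at row {bad}, column {col!r}"
                )
    nan = np.argwhere(~np.isfinite(values.astype(float)))
    if nan.size:
        r, c = nan[0]
        raise ValueError(
            f"{path}: missing value at row {int(r)}, column {feat.columns[int(c)]!r}"
        )
    return FeatureMatrix(values.astype(float), labels, portions)


def write_selection_report(
    outcome: SelectionOutcome,
    path,
    seed: int | None = None,
    cfg: RunConfig | None = None,
) -> None:
    """Per-feature selection report with a '#' metadata header.

    Columns: feature_index, frequency, mean_position, selected (0/1).
    The frequency column sums to the total of the run subset sizes
    (each selection of a feature in a run contributes one count).
    """
    path = Path(path)
    n_features = outcome.frequency.shape[0]
    n_runs = max(len(outcome.runs), 1)
    mean_pos = np.zeros(n_features)
    for run in outcome.runs:
        mean_pos += run.best_position
    mean_pos /= n_runs
    selected = np.zeros(n_features, dtype=int)
    selected[outcome.selected] = 1
    with open(path, "w") as fh:
        fh.write(f"# n_runs: {len(outcome.runs)}\n")
        fh.write(f"# n_avg: {outcome.n_avg}\n")
        fh.write(f"# n1: {outcome.n1}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if cfg is not None:
            fh.write(f"# config_hash: {config_hash(cfg)}\n")
        fh.write("feature_index,frequency,mean_position,selected\n")
        for j in range(n_features):
            fh.write(
                f"{j},{int(outcome.frequency[j])},{repr(float(mean_pos[j]))},"
                f"{selected[j]}\n"
            )


def write_cv_report(report, path) -> None:
    """Fold accuracies plus mean and SD as delimited text."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# mean: {report.mean}\n")
        fh.write(f"# sd: {report.sd}\n")
        fh.write("fold,accuracy\n")
        for i, acc in enumerate(report.fold_accuracies):
            fh.write(f"{i},{repr(float(acc))}\n")
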