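"""GLM feature extraction for block-design BOLD data.

Each stimulus condition is modeled by a boxcar at TR resolution convolved
with the canonical double-gamma hemodynamic response function (SPM
defaults: response peak ~5 s, undershoot ~15 s).  Per run, ordinary least
squares fits the K condition regressors plus an intercept to every voxel's
time series; the resulting K x N beta slice per run stacks into the
M x N feature matrix (M = runs x conditions) that the selection pipeline
consumes, after z-score standardization fit on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .model_eval import FeatureMatrix

__all__ = [
    "HrfParams",
    "DesignMatrix",
    "double_gamma_hrf",
    "build_design_matrix",
    "estimate_betas",
    "zscore_standardize",
    "apply_zscore",
    "features_from_bold",
]


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma HRF parameters (SPM defaults).

    Delays and dispersions are in seconds; the gamma shapes are
    delay/dispersion with scale = dispersion.  ``ratio`` is the
    peak-to-undershoot amplitude ratio; ``length`` the kernel duration;
    ``dt`` the sampling interval (the TR for design construction).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length: float = 32.0
    dt: float = 2.5

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion", "ratio", "length", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HRF parameter {name} must be positive")


def double_gamma_hrf(params: HrfParams = HrfParams()) -> np.ndarray:
    """Sample the double-gamma HRF at ``params.dt`` over ``params.length``.

    h(t) = g(t; peak) - g(t; undershoot)/ratio with gamma densities g,
    normalized to unit peak.  h(0) = 0 since both shapes exceed 1.
    """
    n = int(np.floor(params.length / params.dt)) + 1
    t = np.arange(n) * params.dt
    peak = gamma_dist.pdf(
        t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = gamma_dist.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    h = peak - under / params.ratio
    return h / h.max()


@dataclass
class DesignMatrix:
    """T x (K+1) design: K condition regressors plus a trailing intercept."""

    matrix: np.ndarray
    conditions: list
    run: object = None

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def regressors(self) -> np.ndarray:
        """The condition columns without the intercept."""
        return self.matrix[:, :-1]


def build_design_matrix(
    timing: pd.DataFrame,
    n_volumes: int,
    tr: float,
    hrf: np.ndarray | None = None,
    conditions: list | None = None,
    run=None,
) -> DesignMatrix:
    """Boxcar-convolve stimulus timing into a GLM design.

    ``timing`` needs columns onset_s, duration_s, condition.  Per condition
    a 0/1 boxcar at TR resolution (volume active if its acquisition time
    falls inside a block) is convolved with the HRF kernel and truncated to
    ``n_volumes``.  Overlapping blocks of one condition merge (the boxcar
    saturates at 1).  A constant intercept column is appended.
    """
    if hrf is None:
        hrf = double_gamma_hrf(HrfParams(dt=tr))
    required = {"onset_s", "duration_s", "condition"}
    if not required.issubset(timing.columns):
        raise ValueError(f"timing table must have columns {sorted(required)}")
    if (timing["onset_s"] < 0).any():
        raise ValueError("negative stimulus onset")
    total = n_volumes * tr
    if (timing["onset_s"] >= total).any():
        raise ValueError("stimulus onset beyond the acquired volumes")
    if conditions is None:
        conditions = sorted(timing["condition"].unique())
    times = np.arange(n_volumes) * tr
    columns = []
    for cond in conditions:
        boxcar = np.zeros(n_volumes)
        for _, row in timing[timing["condition"] == cond].iterrows():
            onset, dur = float(row["onset_s"]), float(row["duration_s"])
            boxcar[(times >= onset) & (times < onset + dur)] = 1.0
        columns.append(np.convolve(boxcar, hrf)[:n_volumes])
    design = np.column_stack(columns + [np.ones(n_volumes)])
    return DesignMatrix(matrix=design, conditions=list(conditions), run=run)


def _collinear_columns(x: np.ndarray, names: list) -> list:
    """Columns that are (numerically) linear combinations of earlier ones."""
    bad = []
    for j in range(x.shape[1]):
        if j == 0:
            if np.allclose(x[:, 0], 0):
                bad.append(names[0])
            continue
        prev = x[:, :j]
        coef, *_ = np.linalg.lstsq(prev, x[:, j], rcond=None)
        resid = x[:, j] - prev @ coef
        scale = max(np.linalg.norm(x[:, j]), 1.0)
        if np.linalg.norm(resid) < 1e-8 * scale:
            bad.append(names[j])
    return bad


def estimate_betas(bold: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Per-voxel OLS betas for one run; the intercept row is dropped.

    ``bold`` is T x N (volumes x voxels); the result is K x N.  A
    rank-deficient design raises, naming the collinear columns.
    """
    bold = np.asarray(bold, dtype=float)
    x = design.matrix
    if bold.shape[0] != x.shape[0]:
        raise ValueError(
            f"BOLD has {bold.shape[0]} volumes but design has {x.shape[0]}"
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        names = list(design.conditions) + ["intercept"]
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear columns: {_collinear_columns(x, names)}"
        )
    beta, *_ = np.linalg.lstsq(x, bold, rcond=None)
    return beta[:-1, :]


def zscore_standardize(
    matrix: np.ndarray, fit_rows: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring with statistics fit on ``fit_rows`` only.

    Returns (standardized matrix, mean, sd).  Columns constant over the fit
    rows (sd = 0) map to all zeros rather than dividing by zero.  Applying
    the returned parameters to new rows via :func:`apply_zscore` keeps test
    data out of the statistics (no leakage).
    """
    matrix = np.asarray(matrix, dtype=float)
    if fit_rows is None:
        fit = matrix
    else:
        fit = matrix[fit_rows]
        if fit.size == 0:
            raise ValueError("fit_rows selects no rows")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0)
    return apply_zscore(matrix, mean, sd), mean, sd


def apply_zscore(matrix: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Apply stored z-score parameters; constant columns (sd=0) become 0."""
    safe = np.where(sd > 0, sd, 1.0)
    z = (np.asarray(matrix, dtype=float) - mean) / safe
    z[:, sd == 0] = 0.0
    return z


def features_from_bold(
    bold_runs: np.ndarray,
    timing: pd.DataFrame,
    tr: float,
    hrf: np.ndarray | None = None,
) -> FeatureMatrix:
    """Stack per-run condition betas into the M x N feature matrix.

    ``bold_runs`` is (runs, T, N); ``timing`` needs columns onset_s,
    duration_s, condition, run.  One beta row per (run, condition) —
    labels are condition indices, portions are run ids.
    """
    if "run" not in timing.columns:
        raise ValueError("timing table must have a 'run' column")
    runs = sorted(timing["run"].unique())
    if len(runs) != bold_runs.shape[0]:
        raise ValueError(
            f"timing lists {len(runs)} runs but BOLD has {bold_runs.shape[0]}"
        )
    conditions = sorted(timing["condition"].unique())
    values, labels, portions = [], [], []
    for r_idx, run in enumerate(runs):
        design = build_design_matrix(
            timing[timing["run"] == run],
            n_volumes=bold_runs.shape[1],
            tr=tr,
            hrf=hrf,
            conditions=conditions,
            run=run,
        )
        betas = estimate_betas(bold_runs[r_idx], design)
        for c_idx in range(len(conditions)):
            values.append(betas[c_idx])
            labels.append(c_idx + 1)
            portions.append(run)
    return FeatureMatrix(
        np.asarray(values), np.asarray(labels), np.asarray(portions)
    )
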