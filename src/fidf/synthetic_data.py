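"""Seeded synthetic datasets with the statistical structure the selection
pipeline targets.

Three generators:

* an *additive* multi-class feature matrix with a planted set of
  main-effect features (class-dependent means spaced ``delta`` apart) among
  pure-noise features — what Stage I voxel selection should recover;
* an *interaction* two-class matrix where planted feature pairs are
  sign-coupled (positive product correlation in one class, negative in the
  other) while every marginal stays standard normal in both classes — each
  planted feature alone is uninformative, but its pairwise product column
  separates the classes, which is exactly the structure Stage II
  connectivity selection exists for;
* a *block-design BOLD* simulation (default layout: 12 runs x 8 conditions
  x 9 TRs of 2.5 s per block) driving the GLM front end end-to-end.

All draws come from one generator seeded per call; labels are balanced
exactly across classes and portions (round-robin, so every portion contains
every class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm_features
from .model_eval import FeatureMatrix

__all__ = [
    "SyntheticSpec",
    "BoldDataset",
    "gen_additive_dataset",
    "gen_interaction_dataset",
    "gen_block_bold",
]


@dataclass
class SyntheticSpec:
    """Conditions for the feature-matrix generators.

    ``planted_main`` features carry class-dependent means spaced ``delta``
    apart (in units of the noise SD); ``planted_pairs`` are sign-coupled
    with product correlation ``rho``.  The two planted sets must be
    disjoint.  ``runs`` is the portion count (12, mirroring the 12-run
    outer protocol).
    """

    m: int = 240
    n: int = 100
    k: int = 4
    planted_main: tuple[int, ...] = ()
    delta: float = 2.0
    planted_pairs: tuple[tuple[int, int], ...] = ()
    rho: float = 0.8
    noise_sd: float = 1.0
    runs: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("at least two classes required")
        main = set(self.planted_main)
        paired = {j for pair in self.planted_pairs for j in pair}
        if main & paired:
            raise ValueError("planted main-effect and pair sets must be disjoint")
        for j in main | paired:
            if not (0 <= j < self.n):
                raise ValueError(f"planted feature {j} outside 0..{self.n - 1}")
        for u, v in self.planted_pairs:
            if u == v:
                raise ValueError("a planted pair must couple two distinct features")

    def _balanced_labels(self) -> tuple[np.ndarray, np.ndarray]:
        per_cell, rem = divmod(self.m, self.k * self.runs)
        if rem != 0 or per_cell == 0:
            raise ValueError(
                f"M={self.m} not divisible by K*runs={self.k * self.runs}; "
                "exact class/portion balance infeasible"
            )
        labels = np.empty(self.m, dtype=int)
        portions = np.empty(self.m, dtype=int)
        row = 0
        for p in range(self.runs):          # round-robin: every portion has
            for c in range(self.k):         # every class, equally often
                for _ in range(per_cell):
                    labels[row] = c + 1
                    portions[row] = p
                    row += 1
        return labels, portions


def gen_additive_dataset(spec: SyntheticSpec) -> tuple[FeatureMatrix, list[int]]:
    """Multi-class matrix with planted main-effect features.

    Planted feature j of a class-c instance is drawn
    N((c - (K-1)/2) * delta, noise_sd^2) — adjacent class means sit
    ``delta`` apart.  All other features are N(0, noise_sd^2) noise.
    Returns the matrix and the ground-truth planted index list.
    """
    if spec.delta < 0:
        raise ValueError("delta must be nonnegative")
    rng = np.random.default_rng(spec.seed)
    labels, portions = spec._balanced_labels()
    values = rng.normal(0.0, spec.noise_sd, (spec.m, spec.n))
    offset = (spec.k - 1) / 2.0
    for j in spec.planted_main:
        values[:, j] += ((labels - 1) - offset) * spec.delta
    return (
        FeatureMatrix(values, labels, portions),
        sorted(int(j) for j in spec.planted_main),
    )


def gen_interaction_dataset(
    spec: SyntheticSpec,
) -> tuple[FeatureMatrix, list[tuple[int, int]]]:
    """Two-class matrix with interaction-only (product-informative) pairs.

    For each planted pair (u, v), class 1 draws (u, v) from a bivariate
    normal with correlation +rho and class 2 with -rho; both marginals are
    N(0, 1) in both classes, so neither feature separates the classes on
    its own, while the product column u*v has mean +rho vs -rho.  Returns
    the matrix and the sorted ground-truth pair list.
    """
    if spec.k != 2:
        raise ValueError("the interaction construction is defined for K=2")
    if not (-1.0 < spec.rho < 1.0):
        raise ValueError(f"|rho| must be < 1, got {spec.rho}")
    rng = np.random.default_rng(spec.seed)
    labels, portions = spec._balanced_labels()
    values = rng.normal(0.0, 1.0, (spec.m, spec.n))
    for u, v in spec.planted_pairs:
        for cls, rho in ((1, spec.rho), (2, -spec.rho)):
            rows = np.flatnonzero(labels == cls)
            a = rng.normal(size=rows.size)
            b = rng.normal(size=rows.size)
            values[rows, u] = a
            values[rows, v] = rho * a + np.sqrt(1.0 - rho**2) * b
    pairs = sorted((min(u, v), max(u, v)) for u, v in spec.planted_pairs)
    return FeatureMatrix(values, labels, portions), pairs


@dataclass
class BoldDataset:
    """Simulated block-design BOLD data: (runs, T, N) array, timing table,
    and the true condition-by-voxel beta matrix shared across runs."""

    bold: np.ndarray
    timing: pd.DataFrame
    true_betas: np.ndarray
    tr: float


def gen_block_bold(
    runs: int = 12,
    conditions: int = 8,
    trs_per_block: int = 9,
    tr: float = 2.5,
    n_voxels: int = 20,
    snr: float = 1.0,
    rest_trs: int = 4,
    seed: int = 0,
) -> BoldDataset:
    """Simulate block-design BOLD series through the GLM forward model.

    Per run, the ``conditions`` blocks (each ``trs_per_block`` volumes,
    default 9 TRs of 2.5 s = 22.5 s) appear once in a seeded random order
    separated by ``rest_trs`` rest volumes.  The signal is the
    boxcar-convolved-HRF design times a true beta matrix (N(0,1) entries,
    shared across runs); Gaussian noise is added at the requested SNR
    (signal SD over noise SD; ``snr=inf`` gives noiseless data).
    """
    if min(runs, conditions, trs_per_block, n_voxels) <= 0 or tr <= 0:
        raise ValueError("all dimensions must be positive")
    rng = np.random.default_rng(seed)
    n_volumes = rest_trs + conditions * (trs_per_block + rest_trs)
    hrf = glm_features.double_gamma_hrf(glm_features.HrfParams(dt=tr))
    true_betas = rng.normal(0.0, 1.0, (conditions, n_voxels))
    cond_names = list(range(1, conditions + 1))
    rows = []
    bold = np.empty((runs, n_volumes, n_voxels))
    for r in range(runs):
        order = rng.permutation(conditions)
        t0 = rest_trs * tr
        for cond in order:
            rows.append(
                {
                    "onset_s": t0,
                    "duration_s": trs_per_block * tr,
                    "condition": cond_names[cond],
                    "run": r,
                }
            )
            t0 += (trs_per_block + rest_trs) * tr
        timing_run = pd.DataFrame(rows[-conditions:])
        design = glm_features.build_design_matrix(
            timing_run, n_volumes, tr, hrf=hrf, conditions=cond_names, run=r
        )
        signal = design.regressors() @ true_betas
        if np.isinf(snr):
            noise = 0.0
        else:
            noise_sd = signal.std() / snr if signal.std() > 0 else 1.0 / snr
            noise = rng.normal(0.0, noise_sd, signal.shape)
        bold[r] = signal + noise
    return BoldDataset(
        bold=bold,
        timing=pd.DataFrame(rows),
        true_betas=true_betas,
        tr=tr,
    )
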