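import numpy as np
import pytest

from fidf.model_eval import InnerCVEvaluator
from fidf.swarm_core import SwarmConfig
from fidf.synthetic_data import SyntheticSpec, gen_additive_dataset


@pytest.fixture
def fast_cfg():
    """Small swarm configuration for quick unit-level runs."""
    return SwarmConfig(n=10, layers=5, n_t=30, patience=8, seed=3)


@pytest.fixture
def small_additive():
    """Tiny separable 2-class dataset (12 features, 2 planted) plus its
    ground truth and a cheap inner-CV evaluator."""
    spec = SyntheticSpec(
        m=60, n=12, k=2, planted_main=(0, 1), delta=3.0, runs=10, seed=11
    )
    data, truth = gen_additive_dataset(spec)
    evaluator = InnerCVEvaluator(
        data, repeats=3, rng=7, n_train_portions=6, n_test_portions=4
    )
    return data, truth, evaluator


class CountingEvaluator:
    """Deterministic synthetic error landscape: error depends only on the
    subset, so it stands in for the SVM evaluator in optimizer tests."""

    def __init__(self):
        self.calls = 0

    def __call__(self, subset):
        self.calls += 1
        key = sum((j + 1) ** 2 for j in subset)
        return (key * 0.37) % 1.0


@pytest.fixture
def synthetic_evaluator():
    return CountingEvaluator()
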