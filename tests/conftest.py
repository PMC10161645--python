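"""Shared fixtures.

The heavy end-to-end runs (positive/negative controls, ablations, depth
sweeps) are computed once per session and shared by the validation tests
that assert different properties of the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from modilm.experiments import run_synthetic_experiment
from modilm.simulate import SimSpec

SEEDS = (0, 1, 2, 3, 4)

#: positive-control / sweep study design
POSITIVE_SPEC = SimSpec(n_samples=200, n_classes=3, delta=3.0)
NEGATIVE_SPEC = SimSpec(n_samples=200, n_classes=3, delta=0.0)
MEDIUM_SPEC = SimSpec(n_samples=200, n_classes=3, delta=1.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def positive_runs():
    """Full-model runs on strongly separated synthetic data, 5 seeds."""
    return {s: run_synthetic_experiment(POSITIVE_SPEC, seed=s) for s in SEEDS}


@pytest.fixture(scope="session")
def negative_runs():
    """Same design with zero class separation (label-free data), 5 seeds."""
    return {s: run_synthetic_experiment(NEGATIVE_SPEC, seed=s) for s in SEEDS}


@pytest.fixture(scope="session")
def ablation_runs():
    """Full vs no-GAT vs no-VCDN accuracies on medium-signal data, 5 seeds."""
    out = {}
    for mode in ("full", "no_gat", "no_vcdn"):
        out[mode] = [
            run_synthetic_experiment(MEDIUM_SPEC, seed=s, ablation=mode).metrics.acc
            for s in SEEDS
        ]
    return out
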