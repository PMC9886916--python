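"""Shared fixtures.

The expensive end-to-end runs (full three-stage pipeline at the desk-scale
configuration) are session-scoped so the acceptance-style tests share one
set of trained models across assertions.
"""

from __future__ import annotations

import numpy as np
import pytest

import cslearn
from cslearn.pipeline import TrainingConfig, evaluate_bundle, run_full_pipeline
from cslearn.synthetic_data import SyntheticConfig, make_known_unknown_split


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small dataset for unit tests: K=3 known, U=1 unknown, 10/class, 16x16."""
    cfg = SyntheticConfig(
        image_size=16, n_known_classes=3, n_unknown_classes=1, samples_per_class=10, seed=7
    )
    return cslearn.generate_dataset(cfg)


def desk_run(seed: int):
    """One full desk-scale pipeline run plus its init-only evaluation."""
    config = TrainingConfig.desk_scale(seed=seed)
    dataset = cslearn.generate_dataset(SyntheticConfig.desk_scale(seed=seed))
    bundle, report = run_full_pipeline(dataset, config)
    train, val, unknown = make_known_unknown_split(dataset, seed=config.seed)
    init_report = evaluate_bundle(bundle, train, val, unknown, use_stage1_snapshot=True)
    return {
        "bundle": bundle,
        "report": report,
        "init_report": init_report,
        "dataset": dataset,
        "config": config,
    }


@pytest.fixture(scope="session")
def desk_runs():
    """Full pipeline runs for three seeds (the expensive shared fixture)."""
    return {seed: desk_run(seed) for seed in (1, 2, 3)}
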