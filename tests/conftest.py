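"""Shared fixtures: pre-computed study runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from alarmcal.experiments import StudyConfig, run_synthetic_study
from alarmcal.synthetic import SyntheticParams


@pytest.fixture(scope="session")
def desk_study():
    """Desk-scale risk-control study: 20 experiments, 2,000 series of
    1,000 samples, label window 8, vote window 10, pooling 10, delta 0.1,
    both multiple-testing methods, at the loosest and strictest risk
    levels of the protocol."""
    config = StudyConfig(
        alphas=(0.001, 0.05),
        n_experiments=20,
        synthetic=SyntheticParams(
            event_rate=0.005,
            label_window_len=8,
            flip_prob=0.05,
            series_len=1000,
            n_series=2000,
            seed=0,
        ),
        vote_window_len=10,
        pool_size=10,
        pooling_variants=(True,),
        mhc_methods=("bonferroni", "fixed_sequence"),
        delta=0.1,
        split_fraction=0.5,
        seed=20_240_101,
    )
    return run_synthetic_study(config)


@pytest.fixture(scope="session")
def paired_pooling_study():
    """Smaller study with both pooling variants on shared per-experiment
    data, for paired pooling-vs-no-pooling comparisons (>= 50 pairs)."""
    config = StudyConfig(
        alphas=(0.05,),
        n_experiments=50,
        synthetic=SyntheticParams(
            event_rate=0.005,
            label_window_len=8,
            flip_prob=0.05,
            series_len=800,
            n_series=400,
            seed=0,
        ),
        vote_window_len=10,
        pool_size=10,
        pooling_variants=(False, True),
        mhc_methods=("fixed_sequence",),
        delta=0.1,
        split_fraction=0.5,
        seed=7_654_321,
    )
    return run_synthetic_study(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
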