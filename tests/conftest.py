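"""Shared fixtures: synthetic datasets and trained models.

Training fixtures are session-scoped so the recovery runs are paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecgfewshot import (
    SyntheticClassSpec,
    default_class_specs,
    extract_qrs,
    generate_dataset,
    generate_record,
)
from ecgfewshot.training import TrainingConfig, train_fsl


@pytest.fixture(scope="session")
def clean_record():
    """Noiseless constant-60-BPM record: truth peaks exactly 500 apart."""
    spec = SyntheticClassSpec("clean", bpm_range=(60.0, 60.0), noise_sd=0.0)
    return generate_record(spec, duration=10.0, fs=500.0, seed=1)


@pytest.fixture(scope="session")
def two_class_records():
    """Noiseless 2-class dataset with disjoint morphologies (12 per class)."""
    return generate_dataset(default_class_specs(2, noise_sd=0.0), 12, seed=5)


@pytest.fixture(scope="session")
def two_class_qrs(two_class_records):
    """QRS sets segmented at the generator's ground-truth peaks."""
    return [extract_qrs(r, r.truth_rpeaks) for r in two_class_records]


@pytest.fixture(scope="session")
def recovery_config():
    return TrainingConfig(batch_size=8, max_epochs=200, patience=20, seed=5)


@pytest.fixture(scope="session")
def trained_fsl(two_class_qrs, recovery_config):
    """Few-shot encoder trained to recover the 2-class synthetic structure."""
    model, history = train_fsl(two_class_qrs, recovery_config)
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
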