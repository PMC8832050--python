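"""Shared fixtures: small synthetic datasets and records, generated once."""

import numpy as np
import pytest

from ecgnet import (BeatDataset, LabelTaxonomy, SyntheticConfig,
                    synthesize_dataset, synthesize_record)


@pytest.fixture(scope="session")
def small_dataset():
    """Two-class (H vs A) dataset of 30 beats/class through the real pipeline."""
    ds, gt = synthesize_dataset(["H", "A"], 30, SyntheticConfig(seed=101),
                                beats_per_record=16)
    return ds, gt


@pytest.fixture(scope="session")
def four_class_small():
    """Four-class dataset, 20 beats/class, for split/CV structure tests."""
    ds, _ = synthesize_dataset(["H", "A", "I", "L"], 20, SyntheticConfig(seed=202),
                               beats_per_record=12)
    return ds


@pytest.fixture(scope="session")
def clean_record():
    """One noise- and drift-free healthy record with ground-truth R indices."""
    cfg = SyntheticConfig(seed=7, noise_sd_mv=0.0, drift_amplitude_mv=0.0,
                          beat_rate_hz=1.0)
    rng = np.random.default_rng(7)
    return synthesize_record("H", cfg, rng, n_beats=10, record_id="clean")


@pytest.fixture()
def random_beats():
    """Label-free random windows for container/split mechanics."""
    def make(n, n_classes=1, seed=0, length=651, leads=12):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, length, leads)).astype(np.float32)
        y = rng.integers(0, n_classes, n)
        names = [f"C{i}" for i in range(n_classes)]
        return BeatDataset(X, y, LabelTaxonomy(names))
    return make
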