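from __future__ import annotations

import numpy as np
import pytest

from sevc.features import build_feature_matrix, residue_count_matrix
from sevc.scales import AminoAcidScale, ScaleTable, random_scale
from sevc.simulate import SyntheticConfig, generate_dataset, stratified_split


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic grid: 71 x 8, noise 0.25 x latent sd."""
    constructs, gt = generate_dataset(SyntheticConfig(noise_sd=0.25, seed=1))
    return constructs, gt


@pytest.fixture(scope="session")
def split_dataset(default_dataset):
    constructs, gt = default_dataset
    train_ids, test_ids = stratified_split(constructs, 384, seed=2)
    by_id = {c.id: c for c in constructs}
    train = [by_id[i] for i in train_ids]
    test = [by_id[i] for i in test_ids]
    return {
        "gt": gt,
        "train": train,
        "test": test,
        "train_labels": np.array([c.label for c in train]),
        "test_labels": np.array([c.label for c in test]),
        "train_counts": residue_count_matrix(c.sequence for c in train),
        "train_strategies": [c.strategy_id for c in train],
        "test_strategies": [c.strategy_id for c in test],
    }


@pytest.fixture(scope="session")
def small_panel(split_dataset):
    """Ground-truth scale plus five random scales, with train features."""
    gt = split_dataset["gt"]
    rng = np.random.default_rng(7)
    table = ScaleTable(
        [gt.scale] + [random_scale(rng, name=f"rand{i}") for i in range(5)]
    )
    fm = build_feature_matrix(split_dataset["train"], table)
    return table, fm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_scale():
    return AminoAcidScale.from_array("toy", np.linspace(-1.0, 1.0, 20))
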