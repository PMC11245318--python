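"""Shared fixtures: small molecules, synthetic datasets and trained models.

All data is generated programmatically; the two trained-model fixtures are
session-scoped because NumPy training dominates suite runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from graphadt import (FeaturizerConfig, GraphADTClassifier, SynthConfig,
                      generate_dataset, parse_smiles)


@pytest.fixture(scope="session")
def feat_config() -> FeaturizerConfig:
    return FeaturizerConfig()


@pytest.fixture(scope="session")
def ethanol(feat_config):
    return parse_smiles("CCO", feat_config)


@pytest.fixture(scope="session")
def benzene(feat_config):
    return parse_smiles("c1ccccc1", feat_config)


@pytest.fixture(scope="session")
def small_dataset():
    """Small noiseless planted-toxicophore set for quick fits."""
    return generate_dataset(SynthConfig(n_molecules=80, label_noise=0.0, seed=11))


@pytest.fixture(scope="session")
def tiny_model(small_dataset):
    """A quickly fitted model; adequate for mechanical (not accuracy) checks."""
    clf = GraphADTClassifier(epochs=4, hidden_dim=16, n_layers=2,
                             batch_size=16, random_state=3, val_fraction=0.15)
    clf.fit(small_dataset["smiles"].tolist(), small_dataset["label"].to_numpy())
    return clf


@pytest.fixture(scope="session")
def benchmark_split():
    """The planted-toxicophore benchmark: n=1000, 5% label noise, fixed seed,
    stratified 80/20 train/test split."""
    from sklearn.model_selection import train_test_split

    df = generate_dataset(SynthConfig(n_molecules=1000, label_noise=0.05, seed=7))
    train_df, test_df = train_test_split(
        df, test_size=0.2, stratify=df["label"], random_state=7)
    return train_df.reset_index(drop=True), test_df.reset_index(drop=True)


@pytest.fixture(scope="session")
def trained_model(benchmark_split):
    """Model trained on the benchmark's training fold."""
    train_df, _ = benchmark_split
    clf = GraphADTClassifier(epochs=12, patience=6, random_state=0)
    clf.fit(train_df["smiles"].tolist(), train_df["label"].to_numpy())
    return clf


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
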