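"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from ki67seg import synthetic
from ki67seg.classifier import TileClassifier, TinyBackbone, TrainingConfig, train_head


@pytest.fixture(scope="session")
def tile_dataset():
    """A small three-slide synthetic tile dataset (study-condition defaults)."""
    return synthetic.generate_tile_set(synthetic.SynthSlideParams(seed=1), n_slides=3)


@pytest.fixture(scope="session")
def trained_classifier(tile_dataset):
    """A head trained once on the session dataset, reused across tests."""
    backbone = TinyBackbone(seed=0)
    features = backbone.embed_batch(tile_dataset.pixel_array())
    head, history = train_head(features, tile_dataset.labels(), TrainingConfig(seed=0))
    return TileClassifier(backbone=backbone, head=head), history


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
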