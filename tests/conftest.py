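"""Shared fixtures: one desk-scale synthetic dataset and one trained model
per session, reused by the pipeline-level and acceptance tests."""

import numpy as np
import pytest

from cramnet import model as model_mod
from cramnet import synth

DESK_SEED = 11
TRAIN_SEED = 0


@pytest.fixture(scope="session")
def desk_dataset():
    """~200 train / 50 val / 50 test synthetic 64x64 patches."""
    return synth.generate_dataset(150, (0.667, 0.167, 0.166), 1, seed=DESK_SEED)


@pytest.fixture(scope="session")
def trained_model(desk_dataset):
    """Hybrid model trained from scratch for at most 10 epochs."""
    m = model_mod.build_model(seed=TRAIN_SEED)
    cfg = model_mod.desk_scale_config(seed=TRAIN_SEED, max_epochs=10)
    m, history = model_mod.train(m, desk_dataset, cfg)
    return m, history


@pytest.fixture(scope="session")
def malignant_eval_images(desk_dataset):
    """50 malignant held-out images (test + val) with nonempty masks."""
    pool = [im for im in desk_dataset.test + desk_dataset.val if im.label == synth.MALIGNANT]
    images = pool[:50]
    assert len(images) == 50
    return images


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
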