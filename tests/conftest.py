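"""Shared fixtures. The trained-model fixtures are session-scoped because
a seeded nano training run costs minutes; every test that needs a fitted
regressor shares the same run."""

import numpy as np
import pytest

import vitreg as v

NANO_KW = dict(image_size=64, patch_size=8, depth=4, embed_dim=64, num_heads=2)


@pytest.fixture(scope="session")
def small_samples():
    """A dozen painted phantoms annotated with both rubrics."""
    return v.generate_dataset(12, seed=3, score_types=("GE", "LO"))


@pytest.fixture(scope="session")
def recovery_data():
    """The desk-scale study conditions: 600 training and 150 test
    phantoms with geographic-extent labels."""
    train = v.generate_dataset(600, seed=11, score_types=("GE",))
    test = v.generate_dataset(150, seed=12, score_types=("GE",))
    return train, test


def _xy(samples):
    return [s.image for s in samples], np.array(
        [sum(s.scores["GE"]) for s in samples]
    )


@pytest.fixture(scope="session")
def trained_nano(recovery_data):
    """Nano regressor fitted 30 epochs on the 600 phantoms, augmentation off."""
    train, _ = recovery_data
    x, y = _xy(train)
    reg = v.ViTRegressor(**NANO_KW, epochs=30, cutmix=False, random_state=0)
    reg.fit(x, y)
    return reg


@pytest.fixture(scope="session")
def trained_nano_augmented(recovery_data):
    """Same conditions with both augmentations: offline lung-and-score
    replacement (600 -> 1200 images) plus online score-correlated CutMix."""
    train, _ = recovery_data
    augmented, _records = v.offline_augment(train, ("GE",), seed=5)
    x = [s.image for s in augmented]
    y = np.array([s.global_score for s in augmented])
    reg = v.ViTRegressor(**NANO_KW, epochs=30, cutmix=True, random_state=0)
    reg.fit(x, y)
    return reg
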