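"""Shared fixtures: a small trained surrogate and its stimulus sets.

The fixture scale (12 classes, 16x16 images) is chosen so the whole suite
trains networks and generates adversarial images in seconds while keeping
every stage of the analysis chain non-degenerate (the softmax stage has
>= 10 units, so unit subsampling remains meaningful).
"""

from __future__ import annotations

import numpy as np
import pytest

from advrep.adversarial import generate_adversarial_sets
from advrep.model import train_surrogate
from advrep.synth import generate_image_classes

N_CLASSES = 12
IMAGE_SIZE = 16


@pytest.fixture(scope="session")
def train_set():
    return generate_image_classes(N_CLASSES, 25, IMAGE_SIZE, seed=2)


@pytest.fixture(scope="session")
def surrogate(train_set):
    return train_surrogate(train_set.pixel_array(), train_set.class_ids,
                           epochs=30, seed=0)


@pytest.fixture(scope="session")
def re_set():
    """One regular exemplar per class (the experiment's RE stimulus set)."""
    return generate_image_classes(N_CLASSES, 1, IMAGE_SIZE, seed=3)


@pytest.fixture(scope="session")
def adversarial_sets(surrogate, re_set):
    """(AN set, AI set, diagnostics) generated against the session surrogate."""
    return generate_adversarial_sets(surrogate, re_set, seed=4)


@pytest.fixture()
def rng():
    """A fresh, identically-seeded generator per test: data is deterministic
    and independent of test execution order."""
    return np.random.default_rng(12345)
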