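"""Shared fixtures: small, fast objects for the unit suite."""

import numpy as np
import pytest

from labelrefine import (
    CANONICAL_SCHEME,
    CorruptionSpec,
    TrainConfig,
    build_model,
    corrupt_labels,
    generate_phantom,
)


@pytest.fixture(scope="session")
def scheme():
    return CANONICAL_SCHEME


@pytest.fixture(scope="session")
def phantom():
    """One 32x32 ground-truth phantom."""
    return generate_phantom(seed=11, height=32, width=32)


@pytest.fixture(scope="session")
def phantom_set():
    """Six 32x32 ground-truth phantoms."""
    return [generate_phantom(seed=200 + i, height=32, width=32) for i in range(6)]


@pytest.fixture(scope="session")
def weak_set(phantom_set):
    """Corrupted weak revisions of the phantom set."""
    return [
        corrupt_labels(t, CorruptionSpec(muscle_miss_fraction=0.5, sat_to_vat_band=2,
                                         seed=40 + i))
        for i, t in enumerate(phantom_set)
    ]


@pytest.fixture()
def tiny_model():
    return build_model(channels=1, classes=4, width=4, depth=2, seed=3)


@pytest.fixture()
def tiny_config():
    return TrainConfig(pretrain_epochs=2, finetune_epochs=3, replace_interval=1,
                       batch_size=2, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
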