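"""Shared fixtures.

The trained model bundle is expensive (minutes of CPU), so both stages are
trained once per session on the default synthetic patch datasets and shared
by every test that needs inference.
"""

from __future__ import annotations

import numpy as np
import pytest

from temquant.synth import (default_patch_dataset, default_training_fields,
                            synthesize_vesicle_field)
from temquant.vesnet import ModelBundle, TrainConfig, train_stage

ACCEPT_SEED = 1


@pytest.fixture(scope="session")
def training_fields():
    return default_training_fields(seed=ACCEPT_SEED)

@pytest.fixture(scope="session")
def classify_dataset(training_fields):
    return default_patch_dataset("classify", seed=ACCEPT_SEED,
                                 fields=training_fields)


@pytest.fixture(scope="session")
def segment_dataset(training_fields):
    return default_patch_dataset("segment", seed=ACCEPT_SEED,
                                 fields=training_fields)


@pytest.fixture(scope="session")
def trained_bundle(classify_dataset, segment_dataset) -> ModelBundle:
    """Both detector stages trained under the default regimes."""
    bundle = train_stage(classify_dataset,
                         TrainConfig(stage=1, seed=ACCEPT_SEED))
    bundle = train_stage(segment_dataset,
                         TrainConfig(stage=2, seed=ACCEPT_SEED), bundle)
    return bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def one_vesicle_field():
    """A field containing exactly one clearly isolated vesicle."""
    for seed in range(100):
        img, truth = synthesize_vesicle_field(size_px=128,
                                              density_per_um2=2.5, seed=seed)
        if truth.vesicle_count == 1:
            c = truth.vesicle_centers[0]
            if 30 < c[0] < 98 and 30 < c[1] < 98:
                return img, truth
    raise RuntimeError("no single-vesicle field found")
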