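import numpy as np
import pytest

from tractembed import (ModelConfig, SeqAEModel, TrainConfig,
                        generate_synthetic_atlas, synthetic_atlas_spec,
                        generate_tractogram, train)
from tractembed.synthetic import BundleSpec, SyntheticTractogramSpec


@pytest.fixture(scope="session")
def small_atlas():
    """Desk-scale atlas: 10 bundles x 30 streamlines, fixed seed."""
    return generate_synthetic_atlas(seed=7, n_per_bundle=30)


@pytest.fixture(scope="session")
def two_bundle_spec():
    """One well-separated mirror pair (C-arcs at x = +/-40)."""
    spec = synthetic_atlas_spec(seed=11, n_per_bundle=40)
    return SyntheticTractogramSpec(bundles=(spec.bundles[0],), seed=11)


@pytest.fixture(scope="session")
def two_bundle_tracts(two_bundle_spec):
    return generate_tractogram(two_bundle_spec)


@pytest.fixture(scope="session")
def tiny_model():
    """Small untrained model for shape/determinism checks."""
    return SeqAEModel.initialize(ModelConfig(hidden_dim=8, n_layers=1), seed=0)


@pytest.fixture(scope="session")
def trained_small(two_bundle_tracts):
    """A briefly trained small model on the mirror pair (fast, deterministic)."""
    model = SeqAEModel.initialize(ModelConfig(hidden_dim=16), seed=3)
    best, log = train(model, two_bundle_tracts, TrainConfig(max_epochs=2, seed=3))
    return best, log, two_bundle_tracts
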