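import numpy as np
import pytest

from neuroscore import (
    EncoderConfig,
    PhantomConfig,
    build_encoder,
    generate_phantom_dataset,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small phantom set: 8 subjects/stage x 2 images, 32px slices."""
    return generate_phantom_dataset(
        PhantomConfig(n_subjects_per_stage=8, images_per_subject=2,
                      image_size=32, seed=7)
    )


@pytest.fixture(scope="session")
def small_encoder():
    """Narrow encoder for fast unit tests (architecture unchanged)."""
    return build_encoder(EncoderConfig(feature_dim=32, projection_dim=8, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_unit_vectors(rng, n, d):
    z = rng.normal(size=(n, d))
    return z / np.linalg.norm(z, axis=1, keepdims=True)
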