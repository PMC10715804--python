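import numpy as np
import pytest

from contrawr import EncoderSpec, SyntheticSpec, generate_dataset

# Small fixtures shared across the suite.  Signal epochs are 5 s at 100 Hz
# (N=500) so STFT/conv shapes stay tiny; the encoder is a narrow variant of
# the default architecture.


@pytest.fixture(scope="session")
def tiny_spec() -> EncoderSpec:
    return EncoderSpec(
        stft_window=100,
        stft_hop=50,
        conv_widths=(2, 4, 4, 8),
        proj_hidden=8,
        proj_dim=4,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """8 subjects x 10 epochs, 5 classes, N=500."""
    return generate_dataset(
        SyntheticSpec(n_subjects=8, epochs_per_subject=10, n_samples=500, seed=7)
    )


@pytest.fixture(scope="session")
def two_class_dataset():
    """Widely separated spectral classes (4 Hz vs 16 Hz), 8 x 10 epochs."""
    bands = (((4.0, 1.0, 1.5),), ((16.0, 2.0, 1.5),))
    return generate_dataset(
        SyntheticSpec(
            n_classes=2,
            n_subjects=8,
            epochs_per_subject=10,
            n_samples=500,
            class_bands=bands,
            seed=3,
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
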