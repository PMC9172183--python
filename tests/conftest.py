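"""Shared fixtures: phantoms and a trained segmentation model.

Heavy objects are session-scoped; tests treat them as read-only. Desk-scale
phantoms (48 coronal slices, 96x96 in-plane) keep the suite fast while
preserving every geometric relationship of the full-size default.
"""

import warnings

import numpy as np
import pytest

from lungwater.synthetic import ThoraxTruth, generate_thorax_phantom

warnings.filterwarnings("ignore", category=FutureWarning)

TEST_SHAPE = (48, 96, 96)


@pytest.fixture(scope="session")
def thorax_noise_free():
    """Noise-free default thorax: (volume, labels, realized truth)."""
    return generate_thorax_phantom(ThoraxTruth(shape=TEST_SHAPE, noise_sd=0.0,
                                               seed=1))


@pytest.fixture(scope="session")
def thorax_noisy():
    """Default thorax at 2% noise."""
    return generate_thorax_phantom(ThoraxTruth(shape=TEST_SHAPE, noise_sd=0.02,
                                               seed=1))


@pytest.fixture(scope="session")
def lungs_noise_free(thorax_noise_free):
    from lungwater.segmentation import segment_lungs_classical

    vol, _, _ = thorax_noise_free
    return segment_lungs_classical(vol)


@pytest.fixture(scope="session")
def pipeline_noise_free(thorax_noise_free, lungs_noise_free):
    from lungwater import run_pipeline

    vol, _, _ = thorax_noise_free
    return run_pipeline(vol, "provided", lungs=lungs_noise_free)


@pytest.fixture(scope="session")
def trained_segmenter():
    """Residual U-Net trained on ~200 synthetic slices (<= 20 epochs).

    Returns (model, training log, (images, masks), (train_idx, val_idx)).
    """
    from lungwater.segmentation import train_lung_segmenter

    model, log, data = train_lung_segmenter(n_slices=200, seed=1, epochs=20)
    return model, log, data, model.split_indices
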