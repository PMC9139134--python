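import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from focidens import LabeledObjects


def gaussian_spot(shape, center, peak, sigma):
    yy, xx = np.indices(shape)
    return peak * np.exp(
        -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2.0 * sigma**2)
    )


def quantize8(img):
    """8-bit quantization back to the normalized [0, 1] grid."""
    return np.round(np.clip(img, 0.0, 1.0) * 255) / 255


@pytest.fixture
def single_object_labels():
    """One 40x40 square object centered in a 64x64 frame."""
    labels = np.zeros((64, 64), dtype=np.int32)
    labels[12:52, 12:52] = 1
    return LabeledObjects.from_labels(labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
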