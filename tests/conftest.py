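import numpy as np
import pytest

import vesselforge as vf
from vesselforge.preprocess import build_scale_set, preprocess_frame


@pytest.fixture(scope="session")
def tube_image():
    """Noiseless straight dark vertical tube (width 6) on a bright field."""
    img = np.full((96, 96), 0.8)
    img[:, 45:51] = 0.3
    return img


@pytest.fixture(scope="session")
def scale_set8():
    return build_scale_set(8.0, 10)


@pytest.fixture(scope="session")
def small_pairs():
    """Six small synthetic frames with default study conditions."""
    return vf.generate_dataset(6, seed=11, canvas=(128, 128))


@pytest.fixture(scope="session")
def one_frame(small_pairs):
    angio, mask = small_pairs[0]
    return preprocess_frame(angio), mask


@pytest.fixture(scope="session")
def one_stack(one_frame):
    frame, _ = one_frame
    return vf.extract_filter_features(frame)
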