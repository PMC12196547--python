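import numpy as np
import pytest

from gaitpd import GaitParams, synth_subject


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free dual-view recording with exact landing-frame truth."""
    params = GaitParams(tremor_sd=0.0)
    return synth_subject(params, duration=25.0, seed=42, subject_id="CLEAN")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def coco_sequence(rng):
    """Small random COCO-17 sequence for I/O tests."""
    from gaitpd import KeypointSequence, View

    data = np.empty((7, 17, 3))
    data[:, :, 0] = rng.uniform(0, 1920, (7, 17))
    data[:, :, 1] = rng.uniform(0, 1080, (7, 17))
    data[:, :, 2] = rng.uniform(0, 1, (7, 17))
    return KeypointSequence("sub1", View.LATERAL, data)
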