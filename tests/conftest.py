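import numpy as np
import pytest

from gfacnn.data_io import EEGRecording, EEGSegment
from gfacnn.model import ArchConfig, init_params
from gfacnn.montage import DEFAULT_REGION_MAP, SCALP_CHANNELS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """Two-channel, 512-sample, 256 Hz recording."""
    return EEGRecording(
        signal=rng.normal(0, 10, size=(2, 512)),
        fs=256.0,
        channel_names=["Fp1", "O2"],
        region_map={"Fp1": "frontal", "O2": "occipital"},
    )


@pytest.fixture
def scalp_segment(rng):
    """One 19-channel 1024-sample noise window."""
    return EEGSegment(
        samples=rng.normal(0, 10, size=(19, 1024)),
        fs=256.0,
        channel_names=list(SCALP_CHANNELS),
    )


def make_segment(data, fs=256.0, names=None, label=None):
    n_ch = data.shape[0]
    names = names or list(SCALP_CHANNELS[:n_ch])
    return EEGSegment(samples=data, fs=fs, channel_names=names, label=label)


@pytest.fixture
def tiny_arch():
    """The small fixed architecture used for exact-gradient checks."""
    return ArchConfig(n_nodes=3, feature_dim=4, gcn_dims=(2, 2),
                      dense_dims=(4, 2, 4), n_classes=2)


@pytest.fixture
def tiny_params(tiny_arch):
    return init_params(tiny_arch, seed=7)
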