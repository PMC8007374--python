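import numpy as np
import pytest

from cohnet import CoherenceMatrix, EpochSet, StudyDesign
from cohnet.design import BANDS


@pytest.fixture
def small_design():
    """Fast study layout: 4 subjects, 250 Hz, 10 trials."""
    return StudyDesign(
        n_subjects=4, n_sessions=2, n_trials_per_session=10,
        sampling_rate=250.0, seed=7,
    )


@pytest.fixture
def noise_epochs():
    """19-channel independent-noise EpochSet, 250 Hz, 8 trials of 3 s."""
    rng = np.random.default_rng(11)
    from cohnet.design import CHANNELS_10_20

    data = rng.standard_normal((19, 750, 8)) * 10
    return EpochSet(
        data=data, channel_labels=list(CHANNELS_10_20),
        sampling_rate=250.0, epoch_window=(0.0, 3.0),
    )


def make_epochs(data, fs=250.0, start=0.0, labels=None):
    data = np.asarray(data, float)
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    return EpochSet(
        data=data, channel_labels=labels, sampling_rate=fs,
        epoch_window=(start, start + data.shape[1] / fs),
    )


def make_matrix(values, labels=None, band="full"):
    values = np.asarray(values, float)
    if labels is None:
        labels = [f"n{i}" for i in range(values.shape[0])]
    return CoherenceMatrix(
        values=values, band=BANDS[band], node_labels=labels,
        n_trials_used=1, welch_params=(1.0, 0.5, "hann"),
    )


def random_binary_network(rng, n_nodes, p=0.4, ensure_edge=True):
    from cohnet import BinaryNetwork

    while True:
        a = (rng.random((n_nodes, n_nodes)) < p).astype(int)
        a = np.triu(a, k=1)
        a = a + a.T
        if not ensure_edge or a.sum() > 0:
            return BinaryNetwork(
                adjacency=a, node_labels=[f"n{i}" for i in range(n_nodes)],
                threshold_used=0.5,
            )
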