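import numpy as np
import pytest

from spncoding import synthetic as syn


@pytest.fixture(scope="session")
def short_labels():
    """Two-minute behavior sequence at 40 frames/s covering all behaviors."""
    labels = syn.generate_behavior_sequence(duration_s=120, seed=11)
    assert np.unique(labels.labels).size == 12
    return labels


@pytest.fixture(scope="session")
def short_features(short_labels):
    return syn.generate_feature_series(short_labels, seed=12)


@pytest.fixture(scope="session")
def small_session():
    """A 5-minute, 60-neuron session with planted tuning."""
    labels = syn.generate_behavior_sequence(duration_s=300, seed=21)
    tuning = syn.make_tuning(n_neurons=60, seed=22)
    raster, gt = syn.generate_event_raster(labels, tuning, seed=23)
    return labels, tuning, raster, gt
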