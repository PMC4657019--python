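import numpy as np
import pytest

from audenc import model_spaces, synthetic


@pytest.fixture(scope="session")
def sound_set():
    """Balanced 56 + 28 sound set on the 7-azimuth grid."""
    return synthetic.generate_sound_set(56, 28, 7, seed=101)


@pytest.fixture(scope="session")
def dataset(sound_set):
    """Moderate-noise synthetic dataset with on-grid joint voxel tuning."""
    voxels = synthetic.random_voxels(60, seed=202, noise_sd=0.05, on_grid=True)
    return synthetic.generate_responses(sound_set, voxels, seed=303)


@pytest.fixture(scope="session")
def train_test_matrices(dataset):
    """Joint-model W for the train and test split plus the split responses."""
    tr = dataset.split_indices("train")
    te = dataset.split_indices("test")
    events = dataset.events
    W_train = model_spaces.build_joint(
        [events[i].profile for i in tr], [events[i].azimuth_deg for i in tr]
    )
    W_test = model_spaces.build_joint(
        [events[i].profile for i in te], [events[i].azimuth_deg for i in te]
    )
    return W_train, dataset.Y[tr], W_test, dataset.Y[te]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
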