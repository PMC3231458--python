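import numpy as np
import pytest

import weedvision as wv


@pytest.fixture(scope="session")
def training_data():
    """Separable shape-feature dataset, 54 corn + 65 weed."""
    return wv.generate_feature_dataset(54, 65, overlap=0.0, seed=7)


@pytest.fixture(scope="session")
def trained_model(training_data):
    X, y = training_data
    return wv.train_ann(X, y, seed=3)


@pytest.fixture(scope="session")
def default_scene():
    return wv.generate_scene(wv.SceneParams(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
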