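import numpy as np
import pytest

import mitoflow as mf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def morphology_field():
    """A default-noise still field with 8 objects of each class."""
    stack, truth = mf.make_morphology_field(8, 8, 8, size=(256, 256), seed=7)
    return stack, truth


@pytest.fixture(scope="session")
def eight_feature_library():
    """Training library of eight-feature vectors from three generated fields."""
    X, y = [], []
    for seed in (101, 102, 103):
        stack, truth = mf.make_morphology_field(10, 10, 10, seed=seed)
        for fv in mf.frame_object_features(
            stack.frame(0), truth.label_image, classes=truth.classes
        ):
            X.append(fv.subset(mf.EIGHT_FEATURES))
            y.append(fv.class_label)
    return mf.TrainingLibrary(np.array(X), np.array(y), list(mf.EIGHT_FEATURES))
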