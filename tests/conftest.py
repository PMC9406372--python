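import numpy as np
import pytest

from cytocoral import imagesim
from cytocoral.datasets import Dataset
from cytocoral.types import CLASSES, BethesdaClass, SOURCE_STYLE, TARGET_STYLE


@pytest.fixture(scope="session")
def small_source_dataset() -> Dataset:
    """40 source-domain images (10 per class) at 32px."""
    return Dataset(imagesim.synth_dataset({c: 10 for c in CLASSES},
                                          SOURCE_STYLE, seed=42, size=32))


@pytest.fixture(scope="session")
def small_target_dataset() -> Dataset:
    return Dataset(imagesim.synth_dataset({c: 10 for c in CLASSES},
                                          TARGET_STYLE, seed=43, size=32))


@pytest.fixture(scope="session")
def two_class_arrays():
    """200 well-separated NILM/SCC images at 24px as (X, y)."""
    imgs = imagesim.synth_dataset(
        {BethesdaClass.NILM: 100, BethesdaClass.SCC: 100},
        SOURCE_STYLE, seed=7, size=24)
    X = np.stack([im.pixels for im in imgs])
    y = np.array([0 if im.label == BethesdaClass.NILM else 1 for im in imgs])
    return X, y


def dataset_arrays(ds: Dataset):
    return ds.arrays()
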