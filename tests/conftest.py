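import numpy as np
import pytest

from bacfinder.synthgen import generate_sanity_dataset
from bacfinder.volio import ROI, ROI_SHAPE, LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def asymmetric_roi(rng):
    """An ROI with no flip/transpose symmetry (all 16 transforms distinct)."""
    return ROI(rng.random(ROI_SHAPE), (4, 14, 14), 1, "fishA")


@pytest.fixture
def random_dataset(rng):
    rois = [
        ROI(rng.random(ROI_SHAPE) * 100, (4, 14, 14), int(i % 2), f"fish{i % 2}")
        for i in range(10)
    ]
    return LabeledDataset(rois)


@pytest.fixture(scope="session")
def sanity_dataset():
    return generate_sanity_dataset(200, seed=0, n_datasets=1)
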