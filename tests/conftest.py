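import numpy as np
import pytest

from phf3.config import RunConfig
from phf3.engine import train
from phf3.synth import SyntheticSpec, generate_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_synth():
    """Small synthetic dataset: 40 images/class at 64 px, with lesion masks."""
    images, labels, masks = generate_arrays(SyntheticSpec(n_per_class=40, seed=11))
    return images, labels, masks


@pytest.fixture(scope="session")
def overfit_run(small_synth):
    """A tiny model trained to (near-)perfect accuracy on the small dataset.

    Shared by the evaluation, Grad-CAM and checkpoint tests; training it once
    per session keeps the suite fast.
    """
    images, labels, _ = small_synth
    config = RunConfig.tiny(epochs=16, seed=3)
    result = train(config, images, labels)
    return result, images, labels, config
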