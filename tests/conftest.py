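import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from wildasm.data import DetectionDataset, DetectionSample
from wildasm.scenes import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Eight 96-px synthetic scenes with 3 classes, kept in memory."""
    samples = []
    for i in range(8):
        spec = SceneSpec(image_size=96, n_objects=2, n_classes=3,
                         size_range=(16, 40), clutter_density=0.3,
                         noise_sd=2.0, seed=100 + i)
        img, boxes = generate_scene(spec)
        samples.append(DetectionSample(img, boxes))
    return DetectionDataset(samples, 96, 3)
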