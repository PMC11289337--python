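import numpy as np
import pytest

from valvedet.annotations_io import encode_yolo_box
from valvedet.synth_echo import SynthParams, generate_image
from valvedet.train_eval import DetectionDataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_synth_params():
    """Small frames for fast functional tests."""
    return SynthParams(image_size=96, box_side_range=(12, 18), seed=3)


@pytest.fixture(scope="session")
def overfit_dataset():
    """Eight 192-px synthetic frames with one valve box each.

    Box sides span the anchor-prior range scaled from 768 to 192 px.
    """
    p = SynthParams(image_size=192, box_side_range=(22, 34), seed=7)
    images, labels = [], []
    for i in range(8):
        img, box, _ = generate_image(p, i)
        images.append(img)
        labels.append([encode_yolo_box(box, 192, 192)])
    return DetectionDataset(images, labels, {"train": list(range(8))})
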