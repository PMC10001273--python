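import numpy as np
import pytest

from negdetect import BoundingBox, DatasetManifest, Detection, GroundTruthImage


@pytest.fixture
def rng():
    return np.random.default_rng(20230303)


def make_image(image_id, boxes=(), partition="unassigned", width=100, height=100):
    return GroundTruthImage(
        image_id=image_id, width=width, height=height,
        truth_boxes=[BoundingBox(*b) for b in boxes], partition=partition,
    )


def make_manifest(*images, name="fixture"):
    return DatasetManifest(list(images), name=name)


def det(image_id, box, confidence):
    return Detection(image_id, BoundingBox(*box), confidence)


@pytest.fixture
def single_truth_manifest():
    """One polyp image with one truth box at (10,10)-(30,30)."""
    return make_manifest(make_image("img0", boxes=[(10, 10, 30, 30)]))
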