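import numpy as np
import pytest

from diffsplit import (
    Image,
    InstanceLabelSet,
    InstanceMask,
    Scene,
    SceneParams,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_mask(shape, coords):
    px = np.zeros(shape, dtype=bool)
    for r, c in coords:
        px[r, c] = True
    return InstanceMask(px)


def blob_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return InstanceMask((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2)


@pytest.fixture
def two_blob_scene():
    """16×16 scene with two disjoint circular cells."""
    m1 = blob_mask((16, 16), (4, 4), 2.2)
    m2 = blob_mask((16, 16), (11, 11), 2.8)
    labels = InstanceLabelSet((m1, m2))
    img = np.where(labels.union(), 0.8, 0.1).astype(np.float32)
    return Scene(image=Image(img), labels=labels)


@pytest.fixture
def overlap_scene():
    """16×16 scene with two overlapping circular cells."""
    m1 = blob_mask((16, 16), (7, 5), 3.5)
    m2 = blob_mask((16, 16), (7, 9), 3.5)
    labels = InstanceLabelSet((m1, m2))
    assert np.logical_and(m1.pixels, m2.pixels).any()
    img = np.where(labels.union(), 0.8, 0.1).astype(np.float32)
    return Scene(image=Image(img), labels=labels)


@pytest.fixture(scope="session")
def small_scenes():
    """A handful of default-condition synthetic scenes (two overlapping cells)."""
    return generate_dataset(SceneParams(), 6, seed=2024)


def random_label_set(rng, shape=(24, 24), n_masks=3, allow_overlap=True):
    """Random blobby masks for property tests."""
    masks = []
    for _ in range(n_masks):
        cy, cx = rng.integers(3, shape[0] - 3), rng.integers(3, shape[1] - 3)
        r = rng.uniform(1.5, 4.0)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        px = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if not allow_overlap:
            for m in masks:
                px &= ~m.pixels
        if px.any():
            masks.append(InstanceMask(px))
    if not masks:
        masks = [make_mask(shape, [(1, 1)])]
    return InstanceLabelSet(tuple(masks))
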