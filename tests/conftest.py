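import numpy as np
import pytest

import carrotshape as cs

CLASS_LABELS = {"regular": 1, "irregular": 2}


def disc_mask(radius, pad=10):
    size = 2 * radius + 2 * pad + 1
    yy, xx = np.mgrid[:size, :size]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def rect_mask(height, width, pad=10):
    m = np.zeros((height + 2 * pad, width + 2 * pad), dtype=bool)
    m[pad:pad + height, pad:pad + width] = True
    return m


@pytest.fixture(scope="session")
def standard_dataset():
    """The standard 135-silhouette fixture: 56 regular + 79 irregular,
    generator defaults, seed 2020."""
    samples, table = cs.generate_dataset(56, 79, seed=2020)
    return samples, table


@pytest.fixture(scope="session")
def standard_features(standard_dataset):
    """Segmented and featurised standard fixture: (features DF, labels)."""
    samples, table = standard_dataset
    masks = [cs.segment_image(s.image)[0] for s in samples]
    feats = cs.featurize_masks(masks, index=table.index)
    y = table["shape_class"].map(CLASS_LABELS).to_numpy()
    return feats, y
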