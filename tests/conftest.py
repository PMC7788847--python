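import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from calciquant.phantom import PhantomSpec, generate_phantoms, rotate_augment
from calciquant.segment import TrainConfig, train_segmenter


@pytest.fixture(scope="session")
def phantom_pool():
    """Forty default phantoms: 30 training + 10 test, fixed base seed."""
    return generate_phantoms(40, base_seed=42)


@pytest.fixture(scope="session")
def trained_model(phantom_pool):
    """Segmenter trained on the 120 augmented training phantoms (seed 0).

    Session-scoped because training dominates the suite's runtime; every
    test that needs a fitted model shares this one.
    """
    pairs = [(s.image, s.bone_mask) for s in phantom_pool[:30]]
    augmented = rotate_augment(pairs, 3)
    assert len(augmented) == 120
    return train_segmenter(augmented, TrainConfig(epochs=30, depth=3, seed=0))


@pytest.fixture(scope="session")
def test_phantoms(phantom_pool):
    return phantom_pool[30:]


def match_lesion(measurements, true_centroid):
    """Measured lesion nearest to a ground-truth centroid."""
    best, best_d = None, np.inf
    for m in measurements:
        d = np.hypot(m.centroid[0] - true_centroid[0], m.centroid[1] - true_centroid[1])
        if d < best_d:
            best, best_d = m, d
    return best
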