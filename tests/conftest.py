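import numpy as np
import pytest

from rosettephen import SCHEME_C, SceneParams, SegmentationMask, generate_rosette


def make_mask(labels, scheme=SCHEME_C):
    return SegmentationMask(np.asarray(labels, dtype=np.int64), scheme)


def random_mask(rng, shape, scheme=SCHEME_C):
    return SegmentationMask(
        rng.integers(0, scheme.n_classes, size=shape), scheme
    )


@pytest.fixture(scope="session")
def mixed_scene():
    """A rosette with all three leaf states present."""
    return generate_rosette(
        SceneParams(
            seed=11,
            leaf_count=12,
            state_probabilities=(0.5, 0.3, 0.2),
            background="soil",
        )
    )


@pytest.fixture(scope="session")
def green_scene():
    return generate_rosette(SceneParams(seed=7, background="soil"))
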