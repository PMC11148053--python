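import logging

import numpy as np
import pytest

from udscreen import PhantomConfig, TilingConfig, generate_phantom

logging.disable(logging.WARNING)


SMALL_PHANTOM = dict(
    image_height=512,
    image_width=768,
    n_common=25,
    n_outliers=3,
    min_lesion_gap=35.0,
    n_shadow_regions=1,
)


def small_phantom(seed: int):
    return generate_phantom(PhantomConfig(seed=seed, **SMALL_PHANTOM))


@pytest.fixture(scope="session")
def phantom():
    """One small phantom patient with ground truth (session-cached)."""
    return small_phantom(seed=11)


@pytest.fixture(scope="session")
def full_phantom():
    """Default-scale phantom: 100 common + 5 outlier lesions on 2048x1024."""
    return generate_phantom(PhantomConfig(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fine_tiling():
    """Tiling that exercises multi-tile behavior on the small phantoms."""
    return TilingConfig(tile_size=256, overlap_fraction=0.5)
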