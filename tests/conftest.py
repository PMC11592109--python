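import dataclasses

import numpy as np
import pytest

from evquant.imaging import TileSet, tile
from evquant.simgen import ImageSimConfig, simulate_image_dataset


@pytest.fixture(scope="session")
def small_image_cfg():
    """32x32 images with a handful of spots; fast enough for unit tests."""
    return ImageSimConfig(height=32, width=32, n_spots_range=(2, 5), min_separation=6.0)


@pytest.fixture(scope="session")
def small_tileset(small_image_cfg) -> TileSet:
    """Eight 32x32 tiles with ground-truth masks and counts."""
    ds = simulate_image_dataset(small_image_cfg, 8, seed=5)
    parts = [tile(im.pixels, gt.true_mask, tile_px=32, stride_px=32, out_px=32) for im, gt in zip(ds.images, ds.truths)]
    return TileSet(
        np.concatenate([p.images for p in parts]),
        np.concatenate([p.masks for p in parts]),
        np.concatenate([p.counts for p in parts]),
        sum((p.provenance for p in parts), []),
    )


@pytest.fixture(scope="session")
def noise_free_cfg():
    return dataclasses.replace(ImageSimConfig(), gaussian_sd=0.0)
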