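"""Glue between the simulators, the classical pipeline and the network."""

from __future__ import annotations

import numpy as np

from .imaging import TileSet, augment, extract_green, tile
from .simgen.images import ImageDataset

__all__ = ["dataset_to_tiles"]


def dataset_to_tiles(
    dataset: ImageDataset,
    tile_px: int = 128,
    stride_px: int = 128,
    n_aug: int | None = None,
    seed: int = 0,
) -> TileSet:
    """Tile every image of a simulated dataset against its ground-truth
    mask, optionally augmenting each tile ``n_aug`` times."""
    parts = [
        tile(extract_green(im), gt.true_mask, tile_px=tile_px, stride_px=stride_px)
        for im, gt in zip(dataset.images, dataset.truths)
    ]
    out = TileSet(
        np.concatenate([p.images for p in parts]),
        np.concatenate([p.masks for p in parts]),
        np.concatenate([p.counts for p in parts]),
        sum((p.provenance for p in parts), []),
    )
    if n_aug is not None:
        out = augment(out, n_aug=n_aug, seed=seed)
    return out
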