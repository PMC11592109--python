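"""Classical-CV half of the EV imaging pipeline.

Deterministic preprocessing (green-channel extraction, CLAHE, denoising),
automated ground-truth mask generation from the image's own intensity
distribution, connected-component counting, tiling with a centroid counting
rule, and seeded augmentation.

All operations are pure functions of (input, configuration): running them
twice on the same input yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, measure, morphology, transform

from ._errors import ChannelError, ConfigError

__all__ = [
    "FluorescenceImage",
    "MaskImage",
    "MaskConfig",
    "TileSet",
    "extract_green",
    "clahe",
    "denoise",
    "auto_mask",
    "count_objects",
    "tile",
    "augment",
    "segment_and_count",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FluorescenceImage:
    """A single- or multi-channel fluorescence micrograph.

    Parameters
    ----------
    pixels:
        2-D ``(H, W)`` or 3-D ``(H, W, C)`` intensity array.
    channel_layout:
        Mapping of channel names to indices along the last axis, e.g.
        ``{"green": 1}``.  May be ``None`` for single-channel images.
    intensity_range:
        ``(min, max)`` of the encoding (e.g. ``(0, 65535)`` for 16-bit TIFF).
    """

    pixels: np.ndarray
    channel_layout: dict | None = None
    intensity_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        if px.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D or 3-D")
        lo, hi = self.intensity_range
        if not hi > lo:
            raise ConfigError("intensity_range: max must exceed min")
        object.__setattr__(self, "pixels", px)


def _count_components(binary: np.ndarray, connectivity: int) -> int:
    # skimage connectivity: 1 = 4-neighbour, 2 = 8-neighbour
    conn = 2 if connectivity == 8 else 1
    return int(measure.label(binary, connectivity=conn).max())


@dataclass(frozen=True)
class MaskImage:
    """A binary segmentation mask paired with its connected-component count."""

    pixels: np.ndarray
    connectivity: int = 8

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        uniq = np.unique(px)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary (values in {0, 1})")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity: must be 4 or 8")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def object_count(self) -> int:
        return _count_components(self.pixels, self.connectivity)


@dataclass(frozen=True)
class MaskConfig:
    """Configuration for automated mask generation.

    ``threshold_rule`` selects how the foreground threshold is derived from
    the image's own intensity distribution:

    - ``"mad"``: background mode (median) plus ``k`` robust standard
      deviations (1.4826 * MAD), with a relative floor ``rel_floor`` of the
      dynamic range above background so the rule stays meaningful in the
      noise-free limit where the MAD vanishes;
    - ``"otsu"``: Otsu's between-class variance criterion.
    """

    threshold_rule: str = "mad"
    k: float = 3.0
    rel_floor: float = 0.15
    min_area_px: int = 3
    connectivity: int = 8

    def __post_init__(self):
        if self.threshold_rule not in ("mad", "otsu"):
            raise ConfigError(f"threshold_rule: unknown rule {self.threshold_rule!r}")
        if self.k <= 0:
            raise ConfigError("k: must be positive")
        if not 0 <= self.rel_floor < 1:
            raise ConfigError("rel_floor: must be in [0, 1)")
        if self.min_area_px < 1:
            raise ConfigError("min_area_px: must be >= 1")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity: must be 4 or 8")


@dataclass
class TileSet:
    """Tiles of (image, mask, count) with provenance back to the source image.

    Every tile is exactly ``tile_shape`` (128 x 128 by default); per-tile
    counts follow the centroid rule (a component is counted in the tile that
    contains its centroid, half-open bounds), so counts over non-overlapping
    tiles sum to the whole-image count.
    """

    images: np.ndarray  # (n, 128, 128) float
    masks: np.ndarray  # (n, 128, 128) bool
    counts: np.ndarray  # (n,) int
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.images) == len(self.masks) == len(self.counts)):
            raise ValueError("images, masks and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("per-tile counts must be >= 0")

    def __len__(self) -> int:
        return len(self.images)


# ---------------------------------------------------------------------------
# operations


def extract_green(image: FluorescenceImage) -> np.ndarray:
    """Extract the green channel and rescale to [0, 1].

    Single-channel images pass through the identity path (rescale only).
    """
    px = image.pixels
    if px.ndim == 3:
        if not image.channel_layout or "green" not in image.channel_layout:
            raise ChannelError("image declares no green channel")
        idx = image.channel_layout["green"]
        if not 0 <= idx < px.shape[2]:
            raise ChannelError(f"green channel index {idx} out of range")
        px = px[:, :, idx]
    lo, hi = image.intensity_range
    out = (px.astype(np.float64) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def clahe(channel: np.ndarray, clip_limit: float = 2.0, grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on a [0, 1] channel.

    ``clip_limit`` follows the common convention of a multiple of the uniform
    histogram bin height (2.0 by default); it is converted internally to the
    fractional clip limit used by scikit-image (``clip_limit / nbins`` with
    256 bins).  The contextual grid is ``grid`` tiles over the image.
    """
    if clip_limit <= 0:
        raise ConfigError("clip_limit: must be positive")
    ch = np.asarray(channel, dtype=np.float64)
    if ch.min() < 0 or ch.max() > 1:
        raise ValueError("channel must be scaled to [0, 1]")
    if np.ptp(ch) == 0:  # no contrast to equalise
        return ch.copy()
    kernel = (max(1, ch.shape[0] // grid[0]), max(1, ch.shape[1] // grid[1]))
    frac = min(1.0, clip_limit / 256.0)
    return exposure.equalize_adapthist(ch, kernel_size=kernel, clip_limit=frac, nbins=256)


def denoise(channel: np.ndarray, method: str = "median", param: float = 3) -> np.ndarray:
    """Denoise a [0, 1] channel with a median (size ``param``) or Gaussian
    (sigma ``param``) filter."""
    ch = np.asarray(channel, dtype=np.float64)
    if method == "median":
        size = int(param)
        if size < 1:
            raise ConfigError("param: median window must be >= 1")
        out = ndimage.median_filter(ch, size=size)
    elif method == "gaussian":
        if param < 0:
            raise ConfigError("param: gaussian sigma must be >= 0")
        out = ndimage.gaussian_filter(ch, sigma=float(param))
    else:
        raise ConfigError(f"method: unknown denoise method {method!r}")
    return np.clip(out, 0.0, 1.0)


def _threshold(ch: np.ndarray, cfg: MaskConfig) -> float:
    if cfg.threshold_rule == "otsu":
        from skimage.filters import threshold_otsu

        return float(threshold_otsu(ch))
    med = float(np.median(ch))
    mad = float(np.median(np.abs(ch - med)))
    sigma = 1.4826 * mad
    return med + max(cfg.k * sigma, cfg.rel_floor * (float(ch.max()) - med))


def auto_mask(channel: np.ndarray, cfg: MaskConfig | None = None) -> MaskImage:
    """Threshold a preprocessed channel into a binary mask.

    The threshold is derived only from the image's own intensity
    distribution (see :class:`MaskConfig`); components smaller than
    ``min_area_px`` are removed.  An image with all-equal intensities yields
    an empty mask (no foreground evidence).
    """
    cfg = cfg or MaskConfig()
    ch = np.asarray(channel, dtype=np.float64)
    if ch.size == 0:
        raise ValueError("empty image")
    if np.ptp(ch) == 0:
        return MaskImage(np.zeros(ch.shape, dtype=bool), cfg.connectivity)
    binary = ch > _threshold(ch, cfg)
    conn = 2 if cfg.connectivity == 8 else 1
    if cfg.min_area_px > 1:
        # drop components strictly smaller than min_area_px
        binary = morphology.remove_small_objects(binary, max_size=cfg.min_area_px - 1, connectivity=conn)
    return MaskImage(binary, cfg.connectivity)


def count_objects(mask: MaskImage) -> int:
    """Connected-component count of a binary mask at its declared connectivity."""
    if not isinstance(mask, MaskImage):
        mask = MaskImage(np.asarray(mask))
    return mask.object_count


def _component_centroids(mask: np.ndarray, connectivity: int) -> np.ndarray:
    conn = 2 if connectivity == 8 else 1
    lab = measure.label(mask, connectivity=conn)
    if lab.max() == 0:
        return np.empty((0, 2))
    return np.array([p.centroid for p in measure.regionprops(lab)])


def tile(
    image: np.ndarray,
    mask: MaskImage,
    tile_px: int = 128,
    stride_px: int = 128,
    out_px: int = 128,
) -> TileSet:
    """Cut an image/mask pair into raster-order tiles resized to ``out_px``.

    Masks are resampled nearest-neighbour; the per-tile count is the number
    of mask components whose centroid falls inside the half-open tile bounds
    ``[r0, r0 + tile_px) x [c0, c0 + tile_px)``.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    if tile_px > h or tile_px > w:
        raise ValueError("tile larger than image")
    if stride_px < 1:
        raise ValueError("stride_px must be >= 1")
    mk = mask.pixels
    cents = _component_centroids(mk, mask.connectivity)

    tiles_img, tiles_mask, counts, prov = [], [], [], []
    for r0 in range(0, h - tile_px + 1, stride_px):
        for c0 in range(0, w - tile_px + 1, stride_px):
            sub = img[r0 : r0 + tile_px, c0 : c0 + tile_px]
            sub_m = mk[r0 : r0 + tile_px, c0 : c0 + tile_px]
            if tile_px != out_px:
                sub = transform.resize(sub, (out_px, out_px), order=1, anti_aliasing=True)
                sub_m = (
                    transform.resize(sub_m.astype(float), (out_px, out_px), order=0, anti_aliasing=False) > 0.5
                )
            n = 0
            if len(cents):
                inside = (
                    (cents[:, 0] >= r0)
                    & (cents[:, 0] < r0 + tile_px)
                    & (cents[:, 1] >= c0)
                    & (cents[:, 1] < c0 + tile_px)
                )
                n = int(inside.sum())
            tiles_img.append(sub.astype(np.float32))
            tiles_mask.append(sub_m)
            counts.append(n)
            prov.append({"row": r0, "col": c0, "augmentation": None})
    return TileSet(np.stack(tiles_img), np.stack(tiles_mask), np.asarray(counts), prov)


_DIHEDRAL = [
    lambda a: a,
    lambda a: np.rot90(a, 1),
    lambda a: np.rot90(a, 2),
    lambda a: np.rot90(a, 3),
    lambda a: a[::-1, :],
    lambda a: np.rot90(a[::-1, :], 1),
    lambda a: np.rot90(a[::-1, :], 2),
    lambda a: np.rot90(a[::-1, :], 3),
]


def augment(tileset: TileSet, n_aug: int = 10, seed: int = 0) -> TileSet:
    """Produce ``n_aug`` seeded variants per tile.

    Each variant combines a random dihedral transform (flip/rotation, applied
    identically to image and mask, so counts are unchanged) with a mild
    multiplicative/additive intensity jitter on the image only.
    """
    if n_aug < 1:
        raise ConfigError("n_aug: must be >= 1")
    rng = np.random.default_rng(seed)
    imgs, masks, counts, prov = [], [], [], []
    for i in range(len(tileset)):
        for j in range(n_aug):
            op = int(rng.integers(0, 8))
            gain = rng.uniform(0.9, 1.1)
            offset = rng.uniform(-0.05, 0.05)
            im = _DIHEDRAL[op](tileset.images[i])
            mk = _DIHEDRAL[op](tileset.masks[i])
            im = np.clip(im * gain + offset, 0.0, 1.0).astype(np.float32)
            imgs.append(im)
            masks.append(mk.copy())
            counts.append(tileset.counts[i])
            src = dict(tileset.provenance[i]) if i < len(tileset.provenance) else {}
            src["augmentation"] = (op, j)
            prov.append(src)
    return TileSet(np.stack(imgs), np.stack(masks), np.asarray(counts), prov)


def segment_and_count(
    image: FluorescenceImage | np.ndarray,
    cfg: MaskConfig | None = None,
    denoise_method: str | None = "gaussian",
    denoise_param: float = 0.7,
) -> tuple[MaskImage, int]:
    """Convenience pipeline: green extraction -> denoise -> auto_mask -> count."""
    if isinstance(image, FluorescenceImage):
        ch = extract_green(image)
    else:
        ch = np.clip(np.asarray(image, dtype=np.float64), 0, 1)
    if denoise_method is not None:
        ch = denoise(ch, method=denoise_method, param=denoise_param)
    mask = auto_mask(ch, cfg)
    return mask, mask.object_count
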