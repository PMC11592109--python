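"""Training, inference and random hyperparameter search for the
multitask U-Net.

Losses (weights from :class:`TrainConfig`):

- segmentation: soft Dice loss plus binary cross-entropy on the logits —
  the Dice term handles the heavy foreground/background imbalance of
  sparse spots, the BCE term keeps gradients informative everywhere;
- counting: squared error on ``log1p(count)``, matching the heavy-tailed
  spot-count distribution.

Training is fully seeded: identical (data, configs, seeds) reproduce the
same history.  Early stopping restores the parameters of the best epoch by
composite validation score (Dice minus ``alpha_score`` times the count MAE
normalised by the mean true count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._errors import ConfigError
from ..imaging import TileSet
from .config import ArchConfig, TrainConfig
from .layers import Adam
from .network import MultitaskUNet, build_model

__all__ = ["TrainHistory", "train", "predict", "tune", "count_image"]

_EPS = 1.0  # soft-Dice smoothing


@dataclass
class TrainHistory:
    """Per-epoch losses and validation metrics."""

    table: pd.DataFrame
    best_epoch: int

    def __post_init__(self):
        if not 0 <= self.best_epoch < len(self.table):
            raise ValueError("best_epoch out of range")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _seg_loss_grad(logits, masks):
    """Dice + BCE loss and its gradient with respect to the logits."""
    n = logits.shape[0]
    npix = logits[0].size
    p = _sigmoid(logits)
    m = masks.astype(np.float32)
    # BCE with logits
    bce = np.mean(np.logaddexp(0.0, logits) - m * logits)
    dl_bce = (p - m) / (n * npix)
    # soft Dice per sample
    inter = (p * m).sum(axis=(1, 2))
    sums = p.sum(axis=(1, 2)) + m.sum(axis=(1, 2))
    d = (2 * inter + _EPS) / (sums + _EPS)
    dice_loss = 1.0 - d.mean()
    dd_dp = (2 * m * (sums + _EPS)[:, None, None] - (2 * inter + _EPS)[:, None, None]) / (
        (sums + _EPS) ** 2
    )[:, None, None]
    dl_dice = -(dd_dp * p * (1 - p)) / n
    return bce + dice_loss, (dl_bce + dl_dice).astype(np.float32), float(d.mean())


def _count_loss_grad(y, counts):
    t = np.log1p(counts.astype(np.float64))
    diff = y - t
    loss = float(np.mean(diff**2))
    return loss, (2.0 * diff / len(y)).astype(np.float64)


def _evaluate(model: MultitaskUNet, tiles: TileSet, batch: int = 16):
    """Validation Dice (thresholded at probability > 0.5) and count MAE."""
    dices, preds = [], []
    for i in range(0, len(tiles), batch):
        logits, y = model.forward(tiles.images[i : i + batch])
        pm = _sigmoid(logits) > 0.5
        m = tiles.masks[i : i + batch]
        inter = np.logical_and(pm, m).sum(axis=(1, 2))
        sums = pm.sum(axis=(1, 2)) + m.sum(axis=(1, 2))
        with np.errstate(invalid="ignore"):
            d = np.where(sums > 0, 2 * inter / np.maximum(sums, 1), 1.0)
        dices.extend(d.tolist())
        preds.extend(np.expm1(y).tolist())
    mae = float(np.mean(np.abs(np.asarray(preds) - tiles.counts)))
    return float(np.mean(dices)), mae


def train(
    model: MultitaskUNet,
    train_set: TileSet,
    val_set: TileSet,
    cfg: TrainConfig | None = None,
) -> tuple[MultitaskUNet, TrainHistory]:
    """Train in place; returns the model restored to its best epoch."""
    cfg = cfg or TrainConfig()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    if cfg.init_count_bias and not np.any(model.fc2.b):
        # start the count head at the base rate: softplus(b) = log1p(mean count)
        y0 = max(float(np.log1p(np.mean(train_set.counts))), 1e-3)
        model.fc2.b[...] = np.log(np.expm1(y0))
    opt = Adam(model.params(), lr=cfg.lr)
    mean_count = max(float(np.mean(val_set.counts)), 1.0)

    rows = []
    best_score, best_epoch, best_weights = -np.inf, 0, model.get_weights()
    bad_epochs = 0
    x = train_set.images
    masks = train_set.masks
    counts = train_set.counts
    n = len(train_set)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        tot = seg = cnt = 0.0
        nb = 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits, y = model.forward(x[idx])
            seg_l, dlogits, _ = _seg_loss_grad(logits, masks[idx])
            cnt_l, dy = _count_loss_grad(y, counts[idx])
            loss = cfg.lambda_seg * seg_l + cfg.lambda_count * cnt_l
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {i // cfg.batch_size} "
                    f"(seg={seg_l:.4g}, count={cnt_l:.4g}); try a lower learning rate"
                )
            opt.zero_grad()
            model.backward(cfg.lambda_seg * dlogits, cfg.lambda_count * dy)
            opt.step()
            tot += loss
            seg += seg_l
            cnt += cnt_l
            nb += 1
        val_dice, val_mae = _evaluate(model, val_set, cfg.batch_size)
        score = val_dice - cfg.alpha_score * val_mae / mean_count
        rows.append((epoch, tot / nb, seg / nb, cnt / nb, val_dice, val_mae, score))
        if score > best_score:
            best_score, best_epoch = score, epoch
            best_weights = model.get_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    model.set_weights(best_weights)
    table = pd.DataFrame(
        rows,
        columns=["epoch", "loss", "seg_loss", "count_loss", "val_dice", "val_count_mae", "score"],
    )
    return model, TrainHistory(table=table, best_epoch=best_epoch)


def predict(model: MultitaskUNet, images: np.ndarray, batch: int = 16):
    """Masks (probability strictly above 0.5) and counts for a stack of
    preprocessed tiles."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 3:
        raise ValueError("images must be a stack (n, H, W)")
    masks, counts = [], []
    for i in range(0, len(images), batch):
        logits, y = model.forward(images[i : i + batch])
        masks.append(_sigmoid(logits) > 0.5)
        counts.append(np.expm1(y))
    return np.concatenate(masks), np.concatenate(counts)


def count_image(
    model: MultitaskUNet,
    image: np.ndarray,
    tile_px: int = 128,
    stride_px: int = 128,
) -> float:
    """Whole-image count: sum of per-tile regression outputs, divided by
    the mean per-pixel coverage so overlapping tiles are averaged rather
    than double counted."""
    img = np.asarray(image, dtype=np.float32)
    h, w = img.shape
    tiles = []
    coverage = np.zeros((h, w))
    for r0 in range(0, h - tile_px + 1, stride_px):
        for c0 in range(0, w - tile_px + 1, stride_px):
            tiles.append(img[r0 : r0 + tile_px, c0 : c0 + tile_px])
            coverage[r0 : r0 + tile_px, c0 : c0 + tile_px] += 1
    if not tiles:
        raise ValueError("tile larger than image")
    _, counts = predict(model, np.stack(tiles))
    mean_cov = coverage.sum() / (h * w)
    return float(counts.sum() / mean_cov)


# ---------------------------------------------------------------------------
# random search


def _sample_params(space: dict, rng: np.random.Generator) -> dict:
    """Lists are categorical choices; 2-tuples are numeric ranges
    (log-uniform when both ends are positive)."""
    out = {}
    for name, spec in space.items():
        if isinstance(spec, tuple) and len(spec) == 2 and all(
            isinstance(v, (int, float)) and not isinstance(v, bool) for v in spec
        ):
            lo, hi = spec
            if lo > 0 and hi > 0:
                out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                out[name] = float(rng.uniform(lo, hi))
        elif isinstance(spec, (list, tuple)):
            out[name] = spec[int(rng.integers(0, len(spec)))]
        else:
            out[name] = spec
    return out


def tune(
    dataset: tuple[TileSet, TileSet],
    search_space: dict,
    budget: int = 4,
    seed: int = 0,
) -> tuple[ArchConfig, TrainConfig, pd.DataFrame]:
    """Seeded random search; selection by composite validation score.

    ``search_space`` maps ArchConfig/TrainConfig field names to either a
    list of choices or a numeric (lo, hi) range (log-uniform when both
    ends are positive).  Returns the best configs and the leaderboard.
    """
    if budget < 1:
        raise ConfigError("budget: must be >= 1")
    if not search_space:
        raise ConfigError("search_space: must not be empty")
    train_set, val_set = dataset
    arch_fields = set(ArchConfig.__dataclass_fields__)
    train_fields = set(TrainConfig.__dataclass_fields__)
    unknown = set(search_space) - arch_fields - train_fields
    if unknown:
        raise ConfigError(f"search_space: unknown field(s) {sorted(unknown)}")
    trial_seeds = np.random.SeedSequence(seed).generate_state(budget) % (2**31)
    rows = []
    best = None
    for t in range(budget):
        rng = np.random.default_rng(int(trial_seeds[t]))
        params = _sample_params(search_space, rng)
        arch = ArchConfig(**{k: v for k, v in params.items() if k in arch_fields})
        tcfg = TrainConfig(
            **{k: v for k, v in params.items() if k in train_fields and k != "seed"},
            seed=int(trial_seeds[t]),
        )
        model = build_model(arch, seed=int(trial_seeds[t]))
        try:
            model, hist = train(model, train_set, val_set, tcfg)
            score = float(hist.table["score"].iloc[hist.best_epoch])
        except RuntimeError:  # divergent trial (e.g. absurd learning rate)
            score = -np.inf
        rows.append({"trial": t, "score": score, **params})
        if best is None or score > best[0]:
            best = (score, arch, tcfg)
    leaderboard = pd.DataFrame(rows).sort_values("score", ascending=False).reset_index(drop=True)
    return best[1], best[2], leaderboard
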