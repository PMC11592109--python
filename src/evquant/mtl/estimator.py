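"""sklearn-style estimator facade over the multitask U-Net."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ..imaging import TileSet
from .config import ArchConfig, TrainConfig
from .network import build_model
from .train import _evaluate, predict as _predict, train as _train

__all__ = ["MultitaskSpotCounter"]


class MultitaskSpotCounter(BaseEstimator):
    """Joint spot segmentation and counting, sklearn style.

    ``fit(X, y)`` takes a stack of preprocessed tiles ``X`` of shape
    ``(n, H, W)`` (values in [0, 1], H and W multiples of ``2**depth``)
    and ``y = (masks, counts)``: binary masks ``(n, H, W)`` and integer
    counts ``(n,)``.  ``predict`` returns ``(masks, counts)``.

    Fitted attributes: ``net_`` (the trained network), ``history_``
    (per-epoch metrics), ``best_epoch_``.
    """

    def __init__(
        self,
        encoder: str = "tiny",
        depth: int = 2,
        base_filters: int = 8,
        residual: bool = True,
        lambda_seg: float = 1.0,
        lambda_count: float = 0.5,
        lr: float = 1e-3,
        batch_size: int = 16,
        max_epochs: int = 20,
        patience: int = 6,
        alpha_score: float = 0.5,
        validation_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.encoder = encoder
        self.depth = depth
        self.base_filters = base_filters
        self.residual = residual
        self.lambda_seg = lambda_seg
        self.lambda_count = lambda_count
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.alpha_score = alpha_score
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _configs(self):
        arch = ArchConfig(
            encoder=self.encoder,
            depth=self.depth,
            base_filters=self.base_filters,
            residual=self.residual,
        )
        cfg = TrainConfig(
            lambda_seg=self.lambda_seg,
            lambda_count=self.lambda_count,
            lr=self.lr,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            alpha_score=self.alpha_score,
            seed=self.seed,
        )
        return arch, cfg

    @staticmethod
    def _as_tileset(X, y) -> TileSet:
        masks, counts = y
        return TileSet(
            np.asarray(X, dtype=np.float32),
            np.asarray(masks, dtype=bool),
            np.asarray(counts, dtype=int),
            [],
        )

    def fit(self, X, y, X_val=None, y_val=None):
        arch, cfg = self._configs()
        data = self._as_tileset(X, y)
        if X_val is not None:
            train_set, val_set = data, self._as_tileset(X_val, y_val)
        else:
            rng = np.random.default_rng(self.seed)
            n = len(data)
            n_val = max(1, int(round(self.validation_fraction * n)))
            perm = rng.permutation(n)
            vi, ti = perm[:n_val], perm[n_val:]
            if len(ti) == 0:
                ti = vi
            train_set = TileSet(data.images[ti], data.masks[ti], data.counts[ti], [])
            val_set = TileSet(data.images[vi], data.masks[vi], data.counts[vi], [])
        net = build_model(arch, seed=self.seed)
        net, history = _train(net, train_set, val_set, cfg)
        self.net_ = net
        self.history_ = history.table
        self.best_epoch_ = history.best_epoch
        return self

    def predict(self, X):
        self._check_fitted()
        return _predict(self.net_, np.asarray(X, dtype=np.float32), batch=self.batch_size)

    def score(self, X, y):
        """Composite validation score: Dice - alpha * normalised count MAE."""
        self._check_fitted()
        tiles = self._as_tileset(X, y)
        dice, mae = _evaluate(self.net_, tiles, self.batch_size)
        return dice - self.alpha_score * mae / max(float(np.mean(tiles.counts)), 1.0)

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise AttributeError("estimator is not fitted; call fit first")
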