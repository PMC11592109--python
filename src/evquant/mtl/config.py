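"""Architecture and training configuration."""

from __future__ import annotations

from dataclasses import dataclass

from .._errors import ConfigError


@dataclass(frozen=True)
class ArchConfig:
    """Network architecture.

    ``encoder="tiny"`` is a small from-scratch encoder that trains on a
    CPU in minutes; named pretrained encoder families would require
    downloaded weights, which this runtime does not bundle, so
    ``pretrained=True`` is rejected.
    """

    encoder: str = "tiny"
    pretrained: bool = False
    depth: int = 2
    base_filters: int = 8
    residual: bool = True
    regression_hidden: int = 16
    regression_activation: str = "softplus"

    def __post_init__(self):
        if self.encoder != "tiny":
            raise ConfigError(
                f"encoder: pretrained family {self.encoder!r} is not available in this runtime"
            )
        if self.pretrained:
            raise ConfigError("pretrained: no pretrained weights defined for the tiny encoder")
        if self.depth < 2:
            raise ConfigError("depth: must be >= 2")
        if self.base_filters < 4:
            raise ConfigError("base_filters: must be >= 4")
        if self.regression_hidden < 1:
            raise ConfigError("regression_hidden: must be >= 1")
        if self.regression_activation != "softplus":
            raise ConfigError("regression_activation: only 'softplus' is defined")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.

    The total loss is ``lambda_seg * (dice + bce) + lambda_count * mse`` on
    ``log1p`` counts.  Early stopping monitors the composite validation
    score ``dice - alpha_score * (count MAE / mean true count)``.
    """

    lambda_seg: float = 1.0
    lambda_count: float = 0.5
    lr: float = 2e-3
    batch_size: int = 16
    max_epochs: int = 12
    patience: int = 4
    alpha_score: float = 0.5
    init_count_bias: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.lambda_seg < 0 or self.lambda_count < 0:
            raise ConfigError("lambda_seg/lambda_count: must be >= 0")
        if self.lambda_seg + self.lambda_count <= 0:
            raise ConfigError("lambda_seg + lambda_count: must be positive")
        if self.lr <= 0:
            raise ConfigError("lr: must be positive")
        if self.batch_size < 1:
            raise ConfigError("batch_size: must be >= 1")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs: must be >= 1")
        if not 1 <= self.patience <= self.max_epochs:
            raise ConfigError("patience: must be in [1, max_epochs]")
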