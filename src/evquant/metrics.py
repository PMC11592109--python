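"""Evaluation statistics for segmentation, counting and group comparison.

Dice and IoU follow the usual overlap definitions with the convention that
two empty masks agree perfectly (value 1.0).  ``rank_sum_test`` is the
Mann-Whitney / Wilcoxon rank-sum test for two independent groups: the exact
null distribution is enumerated when the combined sample is small and
tie-free, otherwise a tie-corrected normal approximation with continuity
correction is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .imaging import MaskImage

__all__ = ["SegScores", "CountScores", "dice", "iou", "count_errors", "rank_sum_test"]


@dataclass(frozen=True)
class SegScores:
    dice: float
    iou: float
    per_image: tuple

    def __post_init__(self):
        if not (0 <= self.iou <= self.dice <= 1):
            raise ValueError("need 0 <= iou <= dice <= 1")


@dataclass(frozen=True)
class CountScores:
    mae: float
    mape: float  # percent, truth-zero entries excluded
    bias: float  # mean signed error (pred - truth)
    n_mape_excluded: int = 0


def _as_bool(a) -> np.ndarray:
    px = a.pixels if isinstance(a, MaskImage) else np.asarray(a)
    uniq = np.unique(px)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask must be binary")
    return px.astype(bool)


def dice(a, b) -> float:
    """Dice coefficient 2|A^B| / (|A| + |B|); two empty masks give 1.0."""
    x, y = _as_bool(a), _as_bool(b)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    denom = x.sum() + y.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(x, y).sum() / denom


def iou(a, b) -> float:
    """Intersection over union |A^B| / |AvB|; two empty masks give 1.0."""
    x, y = _as_bool(a), _as_bool(b)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    union = np.logical_or(x, y).sum()
    if union == 0:
        return 1.0
    return np.logical_and(x, y).sum() / union


def seg_scores(pred_masks, true_masks) -> SegScores:
    """Mean Dice/IoU over paired mask lists."""
    pairs = [(dice(p, t), iou(p, t)) for p, t in zip(pred_masks, true_masks)]
    d = float(np.mean([p[0] for p in pairs]))
    j = float(np.mean([p[1] for p in pairs]))
    return SegScores(dice=d, iou=j, per_image=tuple(pairs))


def count_errors(pred, truth) -> CountScores:
    """MAE, MAPE (percent; zero-truth entries excluded) and signed bias."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    if p.size < 1:
        raise ValueError("need at least one pair")
    err = p - t
    nonzero = t != 0
    mape = float(np.mean(np.abs(err[nonzero] / t[nonzero])) * 100) if nonzero.any() else float("nan")
    return CountScores(
        mae=float(np.mean(np.abs(err))),
        mape=mape,
        bias=float(np.mean(err)),
        n_mape_excluded=int((~nonzero).sum()),
    )


# ---------------------------------------------------------------------------
# rank-sum test

EXACT_MAX_N = 12  # combined sample size up to which the exact path is used


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def _exact_null(pooled: np.ndarray, nx: int) -> np.ndarray:
    """Enumerate U over all C(n, nx) assignments of pooled values to group x."""
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    us = []
    for idx in combinations(range(n), nx):
        us.append(ranks[list(idx)].sum() - nx * (nx + 1) / 2.0)
    return np.asarray(us)


def rank_sum_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney rank-sum test for two independent samples.

    Returns ``(U, p)`` where U counts (x > y) pairs (ties as 1/2).  The
    exact p-value is computed by enumerating all label assignments when
    ``len(x) + len(y) <= 12`` and the pooled data are tie-free; otherwise a
    normal approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one observation")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    u = _u_statistic(x, y)
    has_ties = len(np.unique(pooled)) < n

    if n <= EXACT_MAX_N and not has_ties:
        null = _exact_null(pooled, nx)
        m = len(null)
        p_le = np.sum(null <= u + 1e-12) / m
        p_ge = np.sum(null >= u - 1e-12) / m
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif alternative == "greater":
            p = p_ge
        else:
            p = p_le
        return u, float(p)

    mean_u = nx * ny / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:  # all observations identical
        return u, 1.0
    d = u - mean_u
    if alternative == "two-sided":
        z = (abs(d) - 0.5) / np.sqrt(var_u)
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (d - 0.5) / np.sqrt(var_u)
        p = stats.norm.sf(z)
    else:
        z = (d + 0.5) / np.sqrt(var_u)
        p = stats.norm.cdf(z)
    return u, float(min(p, 1.0))
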