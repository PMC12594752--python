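"""Anomaly score maps, image-level scores, threshold fitting and masks.

The pixel-wise score map is the reconstruction error Λ = L_test(x, x̂)
(absolute error by default).  An image-level anomaly score AS aggregates Λ by
one of three rules — global max, global mean, or the max over sliding-patch
means — and an image raises an alarm iff AS > AS*, where AS* is fitted on a
labelled validation set by exhaustive accuracy search.  Flagged images are
segmented by thresholding Λ at λ*, fitted on validation abnormals by Dice
maximisation over a quantile grid.  Both decision rules use strict ">".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_datasets import AnomalyMask, Image

__all__ = [
    "AnomalyScoreMap",
    "Thresholds",
    "AggregatorConfig",
    "score_map",
    "aggregate_score",
    "patch_positions",
    "fit_as_threshold",
    "fit_lambda_threshold",
    "binarize",
    "classify",
]


@dataclass
class AnomalyScoreMap:
    """Per-pixel non-negative reconstruction-error map Λ."""

    values: np.ndarray
    source_image: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("score map must be 2-D")
        if self.values.min() < 0:
            raise ValueError("score map values must be non-negative")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class Thresholds:
    """Fitted decision boundaries: image-level AS* and pixel-level λ*."""

    as_star: float
    lambda_star: float
    provenance: str = ""

    def __post_init__(self):
        if not np.isfinite(self.as_star) or not np.isfinite(self.lambda_star):
            raise ValueError("thresholds must be finite")
        if self.lambda_star < 0:
            raise ValueError("lambda_star must be >= 0")


@dataclass(frozen=True)
class AggregatorConfig:
    method: str = "patch_max"  # max | mean | patch_max
    patch_size: int = 16
    patch_stride: int = 8
    smooth_sigma: float = 0.0  # optional Gaussian smoothing of Λ, off by default


def score_map(x: Image, x_hat: Image, loss: str = "absolute") -> AnomalyScoreMap:
    """Pixel-wise reconstruction error: |x − x̂| or (x − x̂)²."""
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    diff = x.pixels - x_hat.pixels
    if loss == "absolute":
        vals = np.abs(diff)
    elif loss == "squared":
        vals = diff**2
    else:
        raise ValueError(f"unknown loss {loss!r}")
    return AnomalyScoreMap(values=vals, source_image=x.source_path)


def patch_positions(extent: int, patch: int, stride: int) -> list[int]:
    """Sliding-window start offsets with an edge-aligned final window."""
    if patch > extent:
        raise ValueError(f"patch size {patch} exceeds extent {extent}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    pos = list(range(0, extent - patch + 1, stride))
    if pos[-1] != extent - patch:
        pos.append(extent - patch)
    return pos


def aggregate_score(
    smap: AnomalyScoreMap,
    method: str = "max",
    patch_size: int = 16,
    patch_stride: int = 8,
    smooth_sigma: float = 0.0,
) -> float:
    """Scalar anomaly score AS from a score map.

    ``max``: global maximum.  ``mean``: global mean.  ``patch_max``: maximum
    of patch means over a sliding grid (edge-aligned final row/column so every
    pixel lies in at least one patch).
    """
    vals = smap.values
    if smooth_sigma > 0:
        vals = gaussian_filter(vals, sigma=smooth_sigma, mode="reflect")
    if method == "max":
        return float(vals.max())
    if method == "mean":
        return float(vals.mean())
    if method == "patch_max":
        h, w = vals.shape
        if patch_stride > patch_size:
            raise ValueError("patch_stride must not exceed patch_size")
        integ = np.cumsum(np.cumsum(vals, axis=0), axis=1)
        integ = np.pad(integ, ((1, 0), (1, 0)))
        best = -np.inf
        area = patch_size * patch_size
        for i in patch_positions(h, patch_size, patch_stride):
            for j in patch_positions(w, patch_size, patch_stride):
                tot = (
                    integ[i + patch_size, j + patch_size]
                    - integ[i, j + patch_size]
                    - integ[i + patch_size, j]
                    + integ[i, j]
                )
                best = max(best, tot / area)
        return float(best)
    raise ValueError(f"unknown aggregation method {method!r}")


def aggregate_with_config(smap: AnomalyScoreMap, cfg: AggregatorConfig) -> float:
    return aggregate_score(
        smap,
        method=cfg.method,
        patch_size=cfg.patch_size,
        patch_stride=cfg.patch_stride,
        smooth_sigma=cfg.smooth_sigma,
    )


def fit_as_threshold(validation_scores: list[tuple[float, str]]) -> float:
    """Fit the image-level alarm threshold AS*.

    Scans every candidate threshold (midpoints between consecutive sorted
    unique scores, plus one candidate below the minimum and one above the
    maximum) and returns the candidate maximising accuracy of the rule
    "abnormal iff AS > AS*"; ties resolve to the smallest such threshold.
    """
    scores = np.asarray([s for s, _ in validation_scores], dtype=np.float64)
    labels = np.asarray([lab for _, lab in validation_scores])
    if not np.all(np.isin(labels, ("normal", "abnormal"))):
        raise ValueError("labels must be 'normal' or 'abnormal'")
    abnormal = labels == "abnormal"
    if abnormal.all() or (~abnormal).all():
        raise ValueError("validation set must contain both classes")
    uniq = np.unique(scores)
    candidates = [uniq[0] - 1.0]
    candidates += list((uniq[:-1] + uniq[1:]) / 2.0)
    candidates += [uniq[-1] + 1.0]
    best_thr, best_acc = None, -1.0
    for thr in candidates:
        pred = scores > thr
        acc = float(np.mean(pred == abnormal))
        if acc > best_acc:  # strict: first (smallest) threshold wins ties
            best_acc, best_thr = acc, float(thr)
    return best_thr


def fit_lambda_threshold(
    maps: list[AnomalyScoreMap],
    gt_masks: list[AnomalyMask],
    n_grid: int = 200,
) -> float:
    """Fit the pixel-level binarization threshold λ*.

    Evaluates mean Dice over (map, mask) pairs at each candidate λ on a grid
    of ``n_grid`` evenly spaced quantiles of the pooled score values, and
    returns the Dice-maximising λ; ties resolve to the largest λ.
    """
    if len(maps) == 0 or len(maps) != len(gt_masks):
        raise ValueError("need equal, non-zero numbers of maps and masks")
    for m, g in zip(maps, gt_masks):
        if m.shape != g.shape:
            raise ValueError("score map / mask shape mismatch")
    if not any(g.pixels.any() for g in gt_masks):
        raise ValueError("ground truth is empty in every mask")
    pooled = np.concatenate([m.values.ravel() for m in maps])
    grid = np.unique(np.quantile(pooled, np.linspace(0.0, 1.0, n_grid)))
    best_thr, best_dice = None, -1.0
    for lam in grid:
        dices = []
        for m, g in zip(maps, gt_masks):
            pred = m.values > lam
            dices.append(_dice_arrays(pred, g.pixels.astype(bool)))
        mean_dice = float(np.mean(dices))
        if mean_dice >= best_dice:  # >=: largest λ wins ties
            best_dice, best_thr = mean_dice, float(lam)
    return best_thr


def _dice_arrays(pred: np.ndarray, gt: np.ndarray) -> float:
    p, g = int(pred.sum()), int(gt.sum())
    if p + g == 0:
        return 1.0  # both empty
    return 2.0 * int((pred & gt).sum()) / (p + g)


def binarize(smap: AnomalyScoreMap, lambda_star: float) -> AnomalyMask:
    """Pixel mask via strict thresholding: y = 1 iff Λ > λ*."""
    if not np.isfinite(lambda_star):
        raise ValueError("lambda_star must be finite")
    return AnomalyMask(pixels=(smap.values > lambda_star).astype(np.uint8))


def classify(
    smap: AnomalyScoreMap,
    thresholds: Thresholds,
    agg: AggregatorConfig = AggregatorConfig(),
) -> tuple[bool, AnomalyMask | None]:
    """Two-stage decision: alarm iff AS > AS*; segment only alarmed frames."""
    as_value = aggregate_with_config(smap, agg)
    if as_value > thresholds.as_star:
        return True, binarize(smap, thresholds.lambda_star)
    return False, None
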