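"""Benchmark metrics (ACC, AUC, DICE, AUPRC) and per-method reports.

Classification metrics treat "abnormal" as the detection-positive class and
score all test images; segmentation metrics (Dice at λ*, pixel-level AUPRC)
use only the abnormal test samples, which are the only ones with ground-truth
masks.  AUPRC pools pixels across images by default (per-image averaging is
available); it is the interpolation-free step-wise area, and AUC is the
Mann-Whitney rank statistic (equivalently, trapezoidal ROC integration).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .io_datasets import AnomalyMask, DatasetManifest, load_image, load_mask
from .scoring import (
    AggregatorConfig,
    AnomalyScoreMap,
    Thresholds,
    aggregate_with_config,
    binarize,
    score_map,
)

__all__ = [
    "EvaluationReport",
    "accuracy",
    "auroc",
    "dice",
    "auprc",
    "evaluate_method",
    "score_manifest_images",
]


@dataclass
class EvaluationReport:
    """ACC/AUC/DICE/AUPRC bundle for one method on one benchmark."""

    method: str
    acc: float
    auc: float
    dice: float
    auprc: float
    counts: tuple[int, int, int, int]  # TP, TN, FP, FN
    n_images: int
    n_masked_images: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("at least one count must be positive")
    return (tp + tn) / total


def auroc(scores, labels) -> float:
    """Area under the ROC curve; labels are {0,1} with 1 = abnormal."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


def dice(pred: AnomalyMask | np.ndarray, gt: AnomalyMask | np.ndarray) -> float:
    """Dice overlap 2|P∩G| / (|P| + |G|); both-empty convention: 1."""
    p = pred.pixels if isinstance(pred, AnomalyMask) else np.asarray(pred)
    g = gt.pixels if isinstance(gt, AnomalyMask) else np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    p = p.astype(bool)
    g = g.astype(bool)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def auprc(pixel_scores, pixel_labels) -> float:
    """Step-wise (interpolation-free) area under the precision-recall curve."""
    scores = np.asarray(pixel_scores, dtype=np.float64).ravel()
    labels = np.asarray(pixel_labels).ravel()
    if labels.sum() == 0:
        raise ValueError("at least one positive pixel is required")
    return float(average_precision_score(labels, scores))


def score_manifest_images(
    manifest: DatasetManifest,
    model,
    agg: AggregatorConfig,
    loss: str = "absolute",
) -> tuple[list[dict], list[tuple[AnomalyScoreMap, AnomalyMask]]]:
    """Score every test image; returns per-image rows and the (Λ, G) pairs
    for the abnormal samples."""
    rows: list[dict] = []
    neg_pairs: list[tuple[AnomalyScoreMap, AnomalyMask]] = []
    for path in manifest.test_positive:
        img = load_image(path)
        smap = score_map(img, model.reconstruct(img), loss=loss)
        rows.append(
            {"image": str(path), "label": "normal",
             "as_score": aggregate_with_config(smap, agg), "map": smap}
        )
    for path, mask_path in manifest.test_negative:
        img = load_image(path)
        smap = score_map(img, model.reconstruct(img), loss=loss)
        neg_pairs.append((smap, load_mask(mask_path)))
        rows.append(
            {"image": str(path), "label": "abnormal",
             "as_score": aggregate_with_config(smap, agg), "map": smap}
        )
    return rows, neg_pairs


def evaluate_method(
    manifest: DatasetManifest,
    model,
    thresholds: Thresholds,
    agg: AggregatorConfig = AggregatorConfig(),
    loss: str = "absolute",
    pooled_auprc: bool = True,
) -> EvaluationReport:
    """Run one fitted model over a benchmark manifest and report all metrics.

    Alarm rule: AS > AS* (strict).  TP = abnormal image alarmed; TN = normal
    image not alarmed.  Dice is computed at λ* on abnormal samples only.
    """
    if not manifest.test_positive or not manifest.test_negative:
        raise ValueError("manifest must contain both positive and negative test samples")
    rows, neg_pairs = score_manifest_images(manifest, model, agg, loss=loss)

    scores = np.array([r["as_score"] for r in rows])
    is_abnormal = np.array([r["label"] == "abnormal" for r in rows])
    alarmed = scores > thresholds.as_star
    tp = int(np.sum(alarmed & is_abnormal))
    tn = int(np.sum(~alarmed & ~is_abnormal))
    fp = int(np.sum(alarmed & ~is_abnormal))
    fn = int(np.sum(~alarmed & is_abnormal))

    dices = [
        dice(binarize(smap, thresholds.lambda_star), gt) for smap, gt in neg_pairs
    ]
    if pooled_auprc:
        pooled_scores = np.concatenate([s.values.ravel() for s, _ in neg_pairs])
        pooled_labels = np.concatenate([g.pixels.ravel() for _, g in neg_pairs])
        pr_area = auprc(pooled_scores, pooled_labels)
    else:
        areas = [
            auprc(s.values.ravel(), g.pixels.ravel())
            for s, g in neg_pairs
            if g.pixels.any()
        ]
        pr_area = float(np.mean(areas))

    return EvaluationReport(
        method=getattr(model, "name", model.__class__.__name__),
        acc=accuracy(tp, tn, fp, fn),
        auc=auroc(scores, is_abnormal.astype(int)),
        dice=float(np.mean(dices)),
        auprc=pr_area,
        counts=(tp, tn, fp, fn),
        n_images=len(rows),
        n_masked_images=len(neg_pairs),
    )
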