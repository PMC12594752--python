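"""Curation mode: rank an unlabelled image pool by anomaly confidence.

Train a reconstruction model on a small curated normal set, score every image
in a large pool, and sort descending by anomaly score (most suspicious
first).  No threshold is needed — the output is a pure ranking that a curator
reviews from the top — although fitted thresholds can still flag entries.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .io_datasets import IMAGE_EXTENSIONS, load_image
from .scoring import AggregatorConfig, aggregate_with_config, score_map

__all__ = ["RankedPool", "rank_pool"]

logger = logging.getLogger(__name__)


@dataclass
class RankedPool:
    """Pool images ordered by descending anomaly score; rank 1 = most
    suspicious.  ``skipped`` records unreadable files."""

    entries: list[tuple[str, float, int]]  # (path, AS, rank)
    skipped: list[str]

    def __post_init__(self):
        scores = [s for _, s, _ in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("entries must be sorted by non-increasing score")

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["rank", "image", "anomaly_score"])
            for p, s, r in self.entries:
                writer.writerow([r, p, f"{s:.8g}"])


def write_contact_sheet(ranked: RankedPool, path, k: int = 16,
                        which: str = "top") -> None:
    """Tile the k most (``top``) or least (``bottom``) suspicious pool images
    into one 8-bit grid image for visual review."""
    entries = ranked.entries[:k] if which == "top" else ranked.entries[-k:]
    if not entries:
        raise ValueError("ranking is empty")
    imgs = [load_image(p).pixels for p, _, _ in entries]
    h = max(im.shape[0] for im in imgs)
    w = max(im.shape[1] for im in imgs)
    cols = int(np.ceil(np.sqrt(len(imgs))))
    rows = int(np.ceil(len(imgs) / cols))
    sheet = np.ones((rows * h + rows - 1, cols * w + cols - 1))
    for i, im in enumerate(imgs):
        r, c = divmod(i, cols)
        y, x = r * (h + 1), c * (w + 1)
        sheet[y : y + im.shape[0], x : x + im.shape[1]] = im
    iio.imwrite(Path(path), np.round(sheet * 255).astype(np.uint8))


def rank_pool(
    model,
    pool_dir,
    agg: AggregatorConfig = AggregatorConfig(),
    loss: str = "absolute",
) -> RankedPool:
    """Score every readable image under ``pool_dir`` and rank descending.

    Ties break lexicographically by path for reproducibility; unreadable
    files are skipped with a logged warning and recorded in the result.
    """
    pool_dir = Path(pool_dir)
    paths = sorted(
        p for p in pool_dir.rglob("*") if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if not paths:
        raise ValueError(f"no images found under {pool_dir}")
    scored: list[tuple[str, float]] = []
    skipped: list[str] = []
    for p in paths:
        try:
            img = load_image(p)
            smap = score_map(img, model.reconstruct(img), loss=loss)
        except Exception as exc:  # noqa: BLE001 - per-file robustness
            logger.warning("skipping unreadable pool image %s: %s", p, exc)
            skipped.append(str(p))
            continue
        scored.append((str(p), aggregate_with_config(smap, agg)))
    # descending score; lexicographic path breaks ties deterministically
    scored.sort(key=lambda e: (-e[1], e[0]))
    entries = [(p, s, i + 1) for i, (p, s) in enumerate(scored)]
    return RankedPool(entries=entries, skipped=skipped)
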