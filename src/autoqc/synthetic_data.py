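"""Synthetic brightfield-like scenes with injectable quality defects.

Normal scenes emulate high-throughput brightfield fields of sparse dark
cell-like blobs on a bright background.  Five defect classes can be injected
with exact ground-truth masks:

- ``air_bubble``   — dark refractive ring with a brightened interior disc
- ``artifact``     — small dark high-contrast dust blobs / streaks
- ``z_shift``      — global defocus blur (whole-frame mask)
- ``illumination`` — overexposure gain or an uneven additive gradient
                     (whole-frame mask)
- ``contamination``— soft-edged bright spots

Localized defects modify pixels only inside their mask, so the complement of
the mask is bit-identical to the clean image.  Everything is deterministic
given the spec seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_datasets import (
    AnomalyMask,
    DatasetManifest,
    Image,
    save_image,
    save_mask,
    write_manifest,
)

__all__ = [
    "ANOMALY_KINDS",
    "SceneSpec",
    "AnomalySpec",
    "generate_normal",
    "inject_anomaly",
    "make_benchmark",
]

ANOMALY_KINDS = ("air_bubble", "artifact", "z_shift", "illumination", "contamination")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one normal scene; identical specs give identical images."""

    height: int = 64
    width: int = 64
    cell_count: int = 8
    cell_radius_range: tuple[float, float] = (3.0, 6.0)
    background_level: float = 0.75
    cell_darkness: float = 0.35
    noise_sigma: float = 0.02
    seed: int = 0
    polarity: str = "bright"  # bright background/dark cells, or "dark" inverted

    def __post_init__(self):
        if not (0.0 < self.background_level < 1.0):
            raise ValueError("background_level must be in (0, 1)")
        if not (0.0 < self.cell_darkness < 1.0):
            raise ValueError("cell_darkness must be in (0, 1)")
        if self.background_level - self.cell_darkness < 0:
            raise ValueError("cells would undershoot zero intensity")
        if self.cell_count < 0 or self.noise_sigma < 0:
            raise ValueError("cell_count and noise_sigma must be non-negative")
        if self.polarity not in ("bright", "dark"):
            raise ValueError("polarity must be 'bright' or 'dark'")


@dataclass(frozen=True)
class AnomalySpec:
    """One injectable defect.

    ``severity`` in (0, 1] scales the defect strength (contrast depth, blur
    width, gain, spot brightness).  Geometry fields left as ``None`` are
    sampled reproducibly from ``seed``.
    """

    kind: str
    severity: float = 0.75
    seed: int = 0
    center: tuple[float, float] | None = None  # (row, col)
    radius: float | None = None
    n_spots: int | None = None
    angle: float | None = None  # gradient direction / streak angle, radians
    mode: str | None = None  # illumination: "gain" | "gradient"

    def __post_init__(self):
        if self.kind not in ANOMALY_KINDS:
            raise ValueError(f"unknown anomaly kind {self.kind!r}")
        if not (0.0 < self.severity <= 1.0):
            raise ValueError("severity must be in (0, 1]")


def _soft_disc(dist: np.ndarray, radius: float, edge: float = 1.0) -> np.ndarray:
    """1 inside, cosine rolloff of width `edge` at the rim, 0 outside."""
    t = np.clip((radius - dist) / edge, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * t)


def _grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    return np.mgrid[0:h, 0:w].astype(np.float64)


def generate_normal(spec: SceneSpec) -> Image:
    """Render one normal scene: non-overlapping dark elliptical cells with
    smoothed edges on a uniform bright background, plus Gaussian pixel noise.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    canvas = np.full((h, w), spec.background_level, dtype=np.float64)
    rr, cc = _grid(h, w)

    placed: list[tuple[float, float, float]] = []  # (row, col, bounding radius)
    r_lo, r_hi = spec.cell_radius_range
    max_tries = 200 * max(spec.cell_count, 1)
    tries = 0
    while len(placed) < spec.cell_count:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {spec.cell_count} non-overlapping cells "
                f"in a {h}x{w} frame after {max_tries} attempts"
            )
        tries += 1
        a = rng.uniform(r_lo, r_hi)  # semi-axes
        b = rng.uniform(r_lo, r_hi)
        theta = rng.uniform(0, np.pi)
        rb = max(a, b) + 1.0  # bounding radius incl. soft edge
        cy = rng.uniform(rb, h - rb)
        cx = rng.uniform(rb, w - rb)
        if any((cy - py) ** 2 + (cx - px) ** 2 < (rb + pr + 1.0) ** 2 for py, px, pr in placed):
            continue
        placed.append((cy, cx, rb))
        # rotated elliptical radius
        dy, dx = rr - cy, cc - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        profile = 0.5 - 0.5 * np.cos(np.pi * np.clip((1.15 - rho) / 0.3, 0.0, 1.0))
        canvas -= spec.cell_darkness * profile

    if spec.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    canvas = np.clip(canvas, 0.0, 1.0)
    if spec.polarity == "dark":
        canvas = 1.0 - canvas
    return Image(pixels=canvas, bit_depth_origin="float")


def _sample_center(rng, h, w, margin) -> tuple[float, float]:
    return (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))


def _check_in_frame(cy, cx, extent, h, w) -> None:
    if not (0 <= cy - extent and cy + extent <= h and 0 <= cx - extent and cx + extent <= w):
        raise ValueError("anomaly geometry extends outside the image frame")


def inject_anomaly(image: Image, spec: AnomalySpec) -> tuple[Image, AnomalyMask]:
    """Apply one defect; returns the degraded image and its ground-truth mask.

    Localized kinds (air_bubble, artifact, contamination) leave pixels outside
    the returned mask untouched; z_shift and illumination degrade the whole
    frame and return an all-ones mask.
    """
    rng = np.random.default_rng(spec.seed)
    pixels = image.pixels.copy()
    h, w = pixels.shape
    rr, cc = _grid(h, w)
    mask = np.zeros((h, w), dtype=np.uint8)
    s = spec.severity

    if spec.kind == "air_bubble":
        radius = spec.radius if spec.radius is not None else rng.uniform(
            0.12 * min(h, w), 0.3 * min(h, w)
        )
        ring_w = max(1.5, 0.18 * radius)
        extent = radius + ring_w + 1.0
        cy, cx = spec.center if spec.center is not None else _sample_center(
            rng, h, w, extent
        )
        _check_in_frame(cy, cx, extent, h, w)
        dist = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
        ring = np.exp(-0.5 * ((dist - radius) / ring_w) ** 2)
        interior = _soft_disc(dist, radius - ring_w, edge=2.0)
        inside = dist <= radius + ring_w + 1.0
        delta = (-0.6 * s * ring + 0.25 * s * interior) * inside
        pixels = np.clip(pixels + delta, 0.0, 1.0)
        mask = inside.astype(np.uint8)

    elif spec.kind == "artifact":
        n = spec.n_spots if spec.n_spots is not None else int(rng.integers(1, 4))
        support = np.zeros((h, w), dtype=bool)
        delta = np.zeros((h, w), dtype=np.float64)
        for _ in range(max(n, 1)):
            radius = spec.radius if spec.radius is not None else rng.uniform(1.5, 4.0)
            cy, cx = spec.center if spec.center is not None else _sample_center(
                rng, h, w, radius + 2.0
            )
            _check_in_frame(cy, cx, radius, h, w)
            # elongate some blobs into short streaks
            stretch = 1.0 if spec.center is not None else rng.uniform(1.0, 3.0)
            theta = spec.angle if spec.angle is not None else rng.uniform(0, np.pi)
            dy, dx = rr - cy, cc - cx
            u = dx * np.cos(theta) + dy * np.sin(theta)
            v = -dx * np.sin(theta) + dy * np.cos(theta)
            dist = np.sqrt((u / stretch) ** 2 + v**2)
            spot = _soft_disc(dist, radius, edge=1.0)
            sup = dist <= radius + 1.0
            delta = np.minimum(delta, -0.8 * s * spot)
            support |= sup
        pixels = np.clip(pixels + delta * support, 0.0, 1.0)
        mask = support.astype(np.uint8)

    elif spec.kind == "z_shift":
        sigma = 0.5 + 3.5 * s  # defocus blur width in px
        pixels = gaussian_filter(pixels, sigma=sigma, mode="reflect")
        pixels = np.clip(pixels, 0.0, 1.0)
        mask[:] = 1

    elif spec.kind == "illumination":
        mode = spec.mode if spec.mode is not None else rng.choice(["gain", "gradient"])
        if mode == "gain":
            gain = 1.0 + s
            pixels = np.clip(pixels * gain, 0.0, 1.0)
        elif mode == "gradient":
            theta = spec.angle if spec.angle is not None else rng.uniform(0, 2 * np.pi)
            proj = (rr / max(h - 1, 1)) * np.sin(theta) + (cc / max(w - 1, 1)) * np.cos(theta)
            proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-12)
            pixels = np.clip(pixels + 0.6 * s * (proj - 0.5) * 2.0, 0.0, 1.0)
        else:
            raise ValueError(f"unknown illumination mode {mode!r}")
        mask[:] = 1

    elif spec.kind == "contamination":
        n = spec.n_spots if spec.n_spots is not None else int(rng.integers(1, 4))
        support = np.zeros((h, w), dtype=bool)
        delta = np.zeros((h, w), dtype=np.float64)
        for _ in range(max(n, 1)):
            radius = spec.radius if spec.radius is not None else rng.uniform(3.0, 8.0)
            sig = radius / 2.0
            cy, cx = spec.center if spec.center is not None else _sample_center(
                rng, h, w, 2.5 * sig
            )
            _check_in_frame(cy, cx, sig, h, w)
            dist2 = (rr - cy) ** 2 + (cc - cx) ** 2
            bump = 0.6 * s * np.exp(-0.5 * dist2 / sig**2)
            sup = dist2 <= (2.5 * sig) ** 2
            delta = np.maximum(delta, bump)
            support |= sup
        pixels = np.clip(pixels + delta * support, 0.0, 1.0)
        mask = support.astype(np.uint8)

    out = Image(pixels=pixels, source_path=image.source_path, bit_depth_origin="float")
    return out, AnomalyMask(pixels=mask)


@dataclass(frozen=True)
class _BenchmarkLayout:
    train: Path
    test_pos: Path
    neg_images: Path
    neg_masks: Path
    val_normal: Path
    val_abn_images: Path
    val_abn_masks: Path


def _layout(root: Path) -> _BenchmarkLayout:
    return _BenchmarkLayout(
        train=root / "train_normal",
        test_pos=root / "test_positive",
        neg_images=root / "test_negative" / "images",
        neg_masks=root / "test_negative" / "masks",
        val_normal=root / "validation" / "normal",
        val_abn_images=root / "validation" / "abnormal" / "images",
        val_abn_masks=root / "validation" / "abnormal" / "masks",
    )


def make_benchmark(
    out_dir,
    n_train: int,
    n_pos: int,
    n_neg_per_kind: int,
    base_seed: int,
    scene: SceneSpec | None = None,
    severity_range: tuple[float, float] = (0.5, 1.0),
    n_val_normal: int = 0,
    n_val_abnormal_per_kind: int = 0,
    bit_depth: int = 8,
) -> DatasetManifest:
    """Write a complete benchmark (images, masks, YAML manifest) to disk.

    Negative test samples cover the five defect kinds in rotation with
    severities drawn uniformly from ``severity_range``.  Fully reproducible
    from ``base_seed``.
    """
    root = Path(out_dir)
    scene = scene if scene is not None else SceneSpec()
    if n_neg_per_kind == 0:
        warnings.warn(
            "n_neg_per_kind=0: benchmark has no abnormal samples; "
            "classification evaluation will be impossible",
            stacklevel=2,
        )
    lay = _layout(root)
    dirs = [lay.train, lay.test_pos]
    if n_neg_per_kind > 0:
        dirs += [lay.neg_images, lay.neg_masks]
    if n_val_normal > 0:
        dirs.append(lay.val_normal)
    if n_val_abnormal_per_kind > 0:
        dirs += [lay.val_abn_images, lay.val_abn_masks]
    for d in dirs:
        d.mkdir(parents=True, exist_ok=True)

    total = (
        n_train
        + n_pos
        + 5 * n_neg_per_kind
        + n_val_normal
        + 5 * n_val_abnormal_per_kind
    )
    seeds = np.random.SeedSequence(base_seed).generate_state(2 * total + 2)
    next_seed = iter(int(s) % (2**31) for s in seeds)

    manifest = DatasetManifest(root=root)

    def scene_with_seed() -> Image:
        return generate_normal(replace(scene, seed=next(next_seed)))

    def degraded(kind: str) -> tuple[Image, AnomalyMask]:
        img = scene_with_seed()
        sev_rng = np.random.default_rng(next(next_seed))
        sev = float(sev_rng.uniform(*severity_range))
        aspec = AnomalySpec(kind=kind, severity=sev, seed=int(sev_rng.integers(2**31)))
        return inject_anomaly(img, aspec)

    for i in range(n_train):
        p = lay.train / f"train_{i:04d}.tif"
        save_image(scene_with_seed(), p, bit_depth=bit_depth)
        manifest.train_normal.append(p)
    for i in range(n_pos):
        p = lay.test_pos / f"pos_{i:04d}.tif"
        save_image(scene_with_seed(), p, bit_depth=bit_depth)
        manifest.test_positive.append(p)
    for k, kind in enumerate(ANOMALY_KINDS):
        for i in range(n_neg_per_kind):
            img, msk = degraded(kind)
            pi = lay.neg_images / f"neg_{kind}_{i:04d}.tif"
            pm = lay.neg_masks / f"neg_{kind}_{i:04d}.tif"
            save_image(img, pi, bit_depth=bit_depth)
            save_mask(msk, pm)
            manifest.test_negative.append((pi, pm))
    for i in range(n_val_normal):
        p = lay.val_normal / f"val_norm_{i:04d}.tif"
        save_image(scene_with_seed(), p, bit_depth=bit_depth)
        manifest.validation.append((p, "normal", None))
    for kind in ANOMALY_KINDS:
        for i in range(n_val_abnormal_per_kind):
            img, msk = degraded(kind)
            pi = lay.val_abn_images / f"val_abn_{kind}_{i:04d}.tif"
            pm = lay.val_abn_masks / f"val_abn_{kind}_{i:04d}.tif"
            save_image(img, pi, bit_depth=bit_depth)
            save_mask(msk, pm)
            manifest.validation.append((pi, "abnormal", pm))

    write_manifest(manifest, root / "manifest.yaml")
    manifest.validate()
    return manifest
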