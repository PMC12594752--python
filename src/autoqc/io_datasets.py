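"""Image/mask I/O and benchmark dataset layout.

Canonical in-memory form: 2-D float arrays in [0, 1] (bright = 1).  Integer
files are scaled by their dtype maximum (255 or 65535) so absolute intensity
is preserved; float files carry no defined range and are min-max scaled per
image, which discards absolute intensity (a documented caveat).

Default benchmark directory layout::

    root/
      train_normal/            normal training images
      test_positive/           acceptable-quality test images
      test_negative/images/    anomalous test images
      test_negative/masks/     ground-truth masks (same file stems)
      validation/normal/       optional labelled validation images
      validation/abnormal/images/ + validation/abnormal/masks/

An explicit YAML manifest (sections ``train_normal``, ``test_positive``,
``test_negative``, ``validation``) overrides the layout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = [
    "Image",
    "AnomalyMask",
    "DatasetManifest",
    "load_image",
    "load_mask",
    "save_image",
    "save_mask",
    "read_manifest",
    "write_manifest",
]

MIN_SIZE = 32

IMAGE_EXTENSIONS = (".tif", ".tiff", ".png")


class ManifestError(ValueError):
    """Raised for schema or validation problems in a dataset manifest."""


@dataclass
class Image:
    """A normalized 2-D grayscale image, the unit of quality control."""

    pixels: np.ndarray
    source_path: str | None = None
    bit_depth_origin: str = "float"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("Image pixels must be 2-D")
        if self.pixels.shape[0] < MIN_SIZE or self.pixels.shape[1] < MIN_SIZE:
            raise ValueError(
                f"Image must be at least {MIN_SIZE}x{MIN_SIZE}, got {self.pixels.shape}"
            )
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("Image pixels must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class AnomalyMask:
    """Binary mask aligned to an :class:`Image`; 1 marks anomalous pixels."""

    pixels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("AnomalyMask must be 2-D")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("AnomalyMask values must be 0/1")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class DatasetManifest:
    """Resolved file lists for one benchmark dataset."""

    train_normal: list[Path] = field(default_factory=list)
    test_positive: list[Path] = field(default_factory=list)
    test_negative: list[tuple[Path, Path]] = field(default_factory=list)
    validation: list[tuple[Path, str, Path | None]] = field(default_factory=list)
    root: Path | None = None

    def validate(self) -> None:
        for p in self.train_normal + self.test_positive:
            if not Path(p).is_file():
                raise ManifestError(f"missing file: {p}")
        for img, mask in self.test_negative:
            if not Path(img).is_file():
                raise ManifestError(f"missing file: {img}")
            if mask is None or not Path(mask).is_file():
                raise ManifestError(f"missing mask for negative sample: {img}")
        for entry in self.validation:
            img, label, mask = entry
            if label not in ("normal", "abnormal"):
                raise ManifestError(f"bad validation label {label!r} for {img}")
            if not Path(img).is_file():
                raise ManifestError(f"missing file: {img}")
            if mask is not None and not Path(mask).is_file():
                raise ManifestError(f"missing mask: {mask}")


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        # channel axis is whichever axis has length <= 4
        if arr.shape[-1] <= 4:
            arr = arr.mean(axis=-1)
        elif arr.shape[0] <= 4:
            arr = arr.mean(axis=0)
        else:
            raise ValueError("cannot interpret 3-D array as a 2-D grayscale image")
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    return arr


def _read_array(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            return tifffile.imread(path)
        return np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise IOError(f"cannot read image file {path}: {exc}") from exc


def load_image(path: str | os.PathLike, normalize: bool = True) -> Image:
    """Load a TIFF/PNG file as a normalized grayscale :class:`Image`.

    Integer data is divided by the dtype maximum (255 / 65535).  Float data
    carries no defined range: with ``normalize`` it is min-max scaled per
    image (raising on zero dynamic range), without it the values must already
    lie in [0, 1].
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such image file: {path}")
    raw = _read_array(path)
    raw_dtype = raw.dtype  # channel-mean promotes to float; remember the origin
    arr = _to_grayscale(raw)
    if np.issubdtype(raw_dtype, np.integer):
        info = np.iinfo(raw_dtype)
        origin = "8" if info.bits == 8 else "16" if info.bits == 16 else str(info.bits)
        out = arr.astype(np.float64) / info.max
    else:
        origin = "float"
        arr = arr.astype(np.float64)
        if normalize:
            lo, hi = float(arr.min()), float(arr.max())
            if hi - lo <= 0.0:
                raise ValueError(f"degenerate float image (zero dynamic range): {path}")
            out = (arr - lo) / (hi - lo)
        else:
            out = arr
    return Image(pixels=out, source_path=str(path), bit_depth_origin=origin)


def save_image(image: Image | np.ndarray, path: str | os.PathLike, bit_depth: int = 8) -> None:
    """Write a [0,1] image as 8- or 16-bit TIFF/PNG."""
    path = Path(path)
    pixels = image.pixels if isinstance(image, Image) else np.asarray(image)
    if bit_depth == 8:
        data = np.round(np.clip(pixels, 0, 1) * 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(np.clip(pixels, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    _write_array(data, path)


def _write_array(data: np.ndarray, path: Path) -> None:
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, data)
        else:
            iio.imwrite(path, data)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write image file {path}: {exc}") from exc


def save_mask(mask: AnomalyMask, path: str | os.PathLike) -> None:
    """Write a binary mask as an 8-bit image with 0/255 semantics."""
    path = Path(path)
    _write_array((mask.pixels * 255).astype(np.uint8), path)


def load_mask(path: str | os.PathLike) -> AnomalyMask:
    """Load an 8-bit 0/255 mask file; any nonzero pixel counts as anomalous."""
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such mask file: {path}")
    arr = _to_grayscale(_read_array(path))
    return AnomalyMask(pixels=(arr > 0).astype(np.uint8))


def _list_images(d: Path) -> list[Path]:
    return sorted(p for p in d.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS)


def _pair_masks(img_dir: Path, mask_dir: Path) -> list[tuple[Path, Path]]:
    pairs = []
    masks_by_stem = {p.stem: p for p in _list_images(mask_dir)} if mask_dir.is_dir() else {}
    for img in _list_images(img_dir):
        mask = masks_by_stem.get(img.stem)
        if mask is None:
            raise ManifestError(f"missing mask for negative sample: {img}")
        pairs.append((img, mask))
    return pairs


def _manifest_from_directory(root: Path) -> DatasetManifest:
    train_dir = root / "train_normal"
    pos_dir = root / "test_positive"
    neg_dir = root / "test_negative"
    for d, name in ((train_dir, "train_normal"), (pos_dir, "test_positive")):
        if not d.is_dir():
            raise ManifestError(f"missing section directory: {name} under {root}")
    manifest = DatasetManifest(root=root)
    manifest.train_normal = _list_images(train_dir)
    manifest.test_positive = _list_images(pos_dir)
    if (neg_dir / "images").is_dir():
        manifest.test_negative = _pair_masks(neg_dir / "images", neg_dir / "masks")
    val_dir = root / "validation"
    if val_dir.is_dir():
        if (val_dir / "normal").is_dir():
            manifest.validation += [
                (p, "normal", None) for p in _list_images(val_dir / "normal")
            ]
        if (val_dir / "abnormal" / "images").is_dir():
            manifest.validation += [
                (img, "abnormal", mask)
                for img, mask in _pair_masks(
                    val_dir / "abnormal" / "images", val_dir / "abnormal" / "masks"
                )
            ]
    manifest.validate()
    return manifest


def read_manifest(path: str | os.PathLike) -> DatasetManifest:
    """Read a benchmark manifest.

    ``path`` may be a YAML manifest file or a dataset root directory with the
    documented layout.  Relative paths in a manifest file resolve against the
    file's directory.
    """
    path = Path(path)
    if path.is_dir():
        return _manifest_from_directory(path)
    if not path.is_file():
        raise IOError(f"no such manifest: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ManifestError("manifest must be a mapping")
    base = path.parent

    def resolve(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    for section in ("train_normal", "test_positive"):
        if section not in doc:
            raise ManifestError(f"manifest missing section: {section}")
    manifest = DatasetManifest(root=base)
    manifest.train_normal = [resolve(p) for p in doc["train_normal"] or []]
    manifest.test_positive = [resolve(p) for p in doc["test_positive"] or []]
    for entry in doc.get("test_negative") or []:
        if isinstance(entry, dict):
            img, mask = entry.get("image"), entry.get("mask")
        else:
            img, mask = entry
        if mask is None:
            raise ManifestError(f"missing mask for negative sample: {img}")
        manifest.test_negative.append((resolve(img), resolve(mask)))
    for entry in doc.get("validation") or []:
        if isinstance(entry, dict):
            img, label, mask = entry.get("image"), entry.get("label"), entry.get("mask")
        else:
            img, label, mask = (list(entry) + [None])[:3]
        manifest.validation.append(
            (resolve(img), str(label), resolve(mask) if mask else None)
        )
    manifest.validate()
    return manifest


def write_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    """Serialise a manifest to YAML with paths relative to the file."""
    path = Path(path)
    base = path.parent

    def rel(p: Path | None):
        if p is None:
            return None
        try:
            return os.path.relpath(p, base)
        except ValueError:
            return str(p)

    doc = {
        "train_normal": [rel(p) for p in manifest.train_normal],
        "test_positive": [rel(p) for p in manifest.test_positive],
        "test_negative": [
            {"image": rel(i), "mask": rel(m)} for i, m in manifest.test_negative
        ],
        "validation": [
            {"image": rel(i), "label": lab, "mask": rel(m)}
            for i, lab, m in manifest.validation
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
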