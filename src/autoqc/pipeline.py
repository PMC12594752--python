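"""End-to-end glue: train a method, fit thresholds on validation, evaluate.

Used by the `autoqc benchmark` command and by reproduction scripts; keeps the
train -> fit-thresholds -> evaluate protocol in one place so every method is
compared under identical conditions.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .checkpoint import save_model
from .diffusion import DiffusionConfig, NoiseSchedule, train_ddpm, train_pddpm
from .evaluation import EvaluationReport, evaluate_method
from .io_datasets import DatasetManifest, load_image, load_mask, read_manifest
from .recon_models import TrainConfig, train_ae, train_fanogan, train_vae
from .scoring import (
    AggregatorConfig,
    Thresholds,
    aggregate_with_config,
    fit_as_threshold,
    fit_lambda_threshold,
    score_map,
)

__all__ = ["train_method", "fit_thresholds_on_validation", "run_method", "run_benchmark"]


def _diffusion_config(doc: dict, default_seed: int) -> DiffusionConfig:
    schedule = NoiseSchedule.linear(
        doc.get("T", 1000), doc.get("beta_start", 1e-4), doc.get("beta_end", 2e-2)
    )
    return DiffusionConfig(
        schedule=schedule,
        t_test=doc.get("t_test"),
        patch_size=doc.get("patch_size"),
        patch_stride=doc.get("patch_stride"),
        seed=doc.get("seed", default_seed),
    )


def train_method(name: str, images, config: dict | None = None):
    """Train one of the five methods from a plain config dict
    (keys: ``train`` -> TrainConfig fields, ``diffusion`` -> schedule/patch)."""
    config = config or {}
    tcfg = TrainConfig(**config.get("train", {}))
    if name == "ae":
        return train_ae(images, tcfg)
    if name == "vae":
        return train_vae(images, tcfg)
    if name == "fanogan":
        return train_fanogan(images, tcfg)
    if name in ("ddpm", "pddpm"):
        diff = _diffusion_config(config.get("diffusion", {}), tcfg.seed)
        trainer = train_ddpm if name == "ddpm" else train_pddpm
        return trainer(images, tcfg, diff)
    raise ValueError(f"unknown method {name!r}")


def fit_thresholds_on_validation(
    model, manifest: DatasetManifest, agg: AggregatorConfig, loss: str = "absolute"
) -> Thresholds:
    """Fit AS* on labelled validation scores and lambda* on validation
    abnormal samples, per the two-stage workflow."""
    if not manifest.validation:
        raise ValueError("manifest has no validation split to fit thresholds on")
    val_scores = []
    abn_maps, abn_masks = [], []
    for img_path, label, mask_path in manifest.validation:
        img = load_image(img_path)
        smap = score_map(img, model.reconstruct(img), loss=loss)
        val_scores.append((aggregate_with_config(smap, agg), label))
        if label == "abnormal" and mask_path is not None:
            abn_maps.append(smap)
            abn_masks.append(load_mask(mask_path))
    return Thresholds(
        as_star=fit_as_threshold(val_scores),
        lambda_star=fit_lambda_threshold(abn_maps, abn_masks),
        provenance=f"validation split of {manifest.root}",
    )


def run_method(
    name: str,
    manifest: DatasetManifest,
    config: dict | None = None,
    agg: AggregatorConfig = AggregatorConfig(),
) -> tuple[EvaluationReport, Thresholds, object]:
    """Full protocol for one method; returns (report, thresholds, model)."""
    images = [load_image(p) for p in manifest.train_normal]
    model = train_method(name, images, config)
    thresholds = fit_thresholds_on_validation(model, manifest, agg)
    report = evaluate_method(manifest, model, thresholds, agg)
    return report, thresholds, model


def run_benchmark(
    manifest_path,
    model_names: list[str],
    out_dir,
    config: dict | None = None,
    agg: AggregatorConfig = AggregatorConfig(),
) -> list[EvaluationReport]:
    """Run every requested method over one benchmark and write a comparison
    table (CSV) plus per-method checkpoints and reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)
    reports = []
    for name in model_names:
        report, thresholds, model = run_method(name, manifest, config, agg)
        save_model(model, out_dir / f"{name}.npz")
        with open(out_dir / f"{name}_report.json", "w") as fh:
            fh.write(report.to_json())
        reports.append(report)
    with open(out_dir / "comparison.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["method", "acc", "auc", "dice", "auprc"])
        for rep in reports:
            writer.writerow(
                [rep.method, f"{rep.acc:.4f}", f"{rep.auc:.4f}",
                 f"{rep.dice:.4f}", f"{rep.auprc:.4f}"]
            )
    return reports
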