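"""Single-file model checkpoints: weights plus embedded JSON config (.npz)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .diffusion import DDPMModel, DiffusionConfig, NoiseSchedule, PDDPMModel
from .recon_models import AEModel, FAnoGANModel, TrainConfig, VAEModel

__all__ = ["save_model", "load_model", "MODEL_KINDS"]

MODEL_KINDS = ("ae", "vae", "fanogan", "ddpm", "pddpm")


def save_model(model, path) -> None:
    path = Path(path)
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    meta = {"kind": model.name, "config": model.config_dict()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def _rebuild(kind: str, config: dict):
    h, w = config["h"], config["w"]
    tcfg = TrainConfig(**config["train_config"])
    if kind == "ae":
        return AEModel(h, w, tcfg)
    if kind == "vae":
        return VAEModel(h, w, tcfg)
    if kind == "fanogan":
        return FAnoGANModel(h, w, tcfg)
    if kind in ("ddpm", "pddpm"):
        d = config["diffusion"]
        diff = DiffusionConfig(
            schedule=NoiseSchedule.linear(d["T"], d["beta_start"], d["beta_end"]),
            t_test=d["t_test"],
            patch_size=d["patch_size"],
            patch_stride=d["patch_stride"],
            seed=d["seed"],
        )
        cls = DDPMModel if kind == "ddpm" else PDDPMModel
        return cls(h, w, tcfg, diff)
    raise ValueError(f"unknown model kind {kind!r}")


def load_model(path):
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such checkpoint: {path}")
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        keys = sorted(k for k in data.files if k.startswith("param_"))
        arrays = [data[k] for k in keys]
    model = _rebuild(meta["kind"], meta["config"])
    model.load_state_arrays(arrays)
    return model
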