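"""Desk-scale study presets: one place for the benchmark conditions and the
model configurations used by the bundled reproduction script and the
end-to-end tests.

The synthetic benchmark is 64x64 px with 32 training normals, 16 positive
test samples, 2 negatives per anomaly kind and a labelled validation split
(8 normals + 1 abnormal per kind) for threshold fitting.  The diffusion
profile compresses the schedule to T = 100 steps with beta_end scaled up so
the total accumulated noise matches the conventional long schedule.
"""

from __future__ import annotations

from .io_datasets import DatasetManifest
from .synthetic_data import SceneSpec, make_benchmark

__all__ = [
    "DESK_SCENE",
    "desk_benchmark",
    "desk_pddpm_config",
    "desk_ae_config",
    "DESK_AGG",
]

DESK_SCENE = SceneSpec()  # 64x64, 8 cells, bright background

# patch_max over 16 px windows, half-overlapping
DESK_AGG = dict(method="patch_max", patch_size=16, patch_stride=8)


def desk_benchmark(out_dir, seed: int) -> DatasetManifest:
    """Generate the desk-scale benchmark (train 32 / pos 16 / neg 2 x 5 kinds,
    validation 8 + 5)."""
    return make_benchmark(
        out_dir,
        n_train=32,
        n_pos=16,
        n_neg_per_kind=2,
        base_seed=seed,
        scene=DESK_SCENE,
        n_val_normal=8,
        n_val_abnormal_per_kind=1,
    )


def desk_pddpm_config(seed: int = 0, epochs: int = 600) -> dict:
    """Patch-diffusion profile: T=100 compressed schedule, reconstruction at
    t_test=15, 16 px patches with half-overlap."""
    return {
        "train": {
            "epochs": epochs,
            "batch_size": 8,
            "learning_rate": 2e-3,
            "base_width": 8,
            "n_levels": 2,
            "seed": seed,
        },
        "diffusion": {
            "T": 100,
            "beta_start": 1e-3,
            "beta_end": 0.2,
            "t_test": 15,
            "patch_size": 16,
            "patch_stride": 8,
            "seed": seed,
        },
    }


def desk_ae_config(seed: int = 0, epochs: int = 300) -> dict:
    """Autoencoder baseline sized comparably to the diffusion profile."""
    return {
        "train": {
            "epochs": epochs,
            "batch_size": 8,
            "learning_rate": 2e-3,
            "latent_dim": 64,
            "base_width": 8,
            "n_levels": 3,
            "corruption_noise_sigma": 0.1,
            "seed": seed,
        }
    }
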