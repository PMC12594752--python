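"""Shared training configuration and the reconstruction-model contract."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from ..io_datasets import Image
from ..nn import Tensor

__all__ = ["TrainConfig", "ReconstructionModel", "stack_images", "pnorm_loss"]


@dataclass
class TrainConfig:
    """Hyperparameters shared by all reconstruction baselines.

    ``corruption_noise_sigma`` is the std of the additive Gaussian corruption
    applied to training inputs (the target stays clean); 0 recovers plain
    autoencoding.  ``p_norm`` selects the reconstruction norm (1 or 2).
    VAE: ``kl_weight``.  f-AnoGAN: ``kappa`` (feature-residual weight),
    ``critic_steps`` and ``gp_weight`` (WGAN-GP practice).
    """

    epochs: int = 150
    batch_size: int = 8
    learning_rate: float = 1e-3
    latent_dim: int = 64
    corruption_noise_sigma: float = 0.1
    p_norm: int = 1
    seed: int = 0
    base_width: int = 32
    n_levels: int = 4
    kl_weight: float = 1.0
    kappa: float = 1.0
    critic_steps: int = 5
    gp_weight: float = 10.0

    def __post_init__(self):
        if self.p_norm not in (1, 2):
            raise ValueError("p_norm must be 1 or 2")
        for name in ("epochs", "batch_size", "latent_dim", "base_width", "n_levels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.corruption_noise_sigma < 0:
            raise ValueError("corruption_noise_sigma must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def stack_images(images: list[Image]) -> np.ndarray:
    """Stack Images into an (N, 1, H, W) float32 batch; shapes must agree."""
    if len(images) == 0:
        raise ValueError("need at least one image")
    shapes = {img.shape for img in images}
    if len(shapes) != 1:
        raise ValueError(f"all training images must share one shape, got {shapes}")
    return np.stack([img.pixels[None] for img in images]).astype(np.float32)


def pnorm_loss(diff: Tensor, p: int) -> Tensor:
    """Mean over the batch of the per-image p-norm of `diff` (N,1,H,W)."""
    if p == 1:
        return diff.abs().sum(axis=(1, 2, 3)).mean()
    return ((diff**2.0).sum(axis=(1, 2, 3)) + 1e-12).sqrt().mean()


class ReconstructionModel:
    """Contract shared by all five model families.

    ``reconstruct`` maps an Image to a same-shape Image with values in
    [0, 1] and is deterministic in inference mode (stochastic encoders use
    the mean code; diffusion models use a seeded noise draw).
    """

    name: str = "base"

    def reconstruct(self, image: Image) -> Image:
        raise NotImplementedError

    def reconstruct_batch(self, pixels: np.ndarray) -> np.ndarray:
        """(N,1,H,W) in [0,1] -> same-shape reconstruction in [0,1]."""
        raise NotImplementedError

    # serialisation interface used by autoqc.checkpoint
    def state_arrays(self) -> list[np.ndarray]:
        raise NotImplementedError

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        raise NotImplementedError

    def config_dict(self) -> dict:
        raise NotImplementedError

    def _reconstruct_single(self, image: Image) -> Image:
        batch = image.pixels[None, None].astype(np.float32)
        out = self.reconstruct_batch(batch)[0, 0]
        return Image(
            pixels=np.clip(out.astype(np.float64), 0.0, 1.0),
            source_path=image.source_path,
            bit_depth_origin=image.bit_depth_origin,
        )


def check_finite(loss_value: float, what: str) -> None:
    if not np.isfinite(loss_value):
        raise FloatingPointError(f"{what} diverged: non-finite loss")


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]
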