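"""Denoising convolutional autoencoder baseline.

Trained to reconstruct the clean image from an input corrupted by additive
Gaussian noise, minimising the mean per-image p-norm of the residual.
"""

from __future__ import annotations

import numpy as np

from ..io_datasets import Image
from ..nn import Adam, Tensor
from .base import (
    ReconstructionModel,
    TrainConfig,
    check_finite,
    minibatches,
    pnorm_loss,
    stack_images,
)
from .nets import ConvDecoder, ConvEncoder

__all__ = ["AEModel", "train_ae"]


class AEModel(ReconstructionModel):
    name = "ae"

    def __init__(self, h: int, w: int, cfg: TrainConfig):
        self.h, self.w = h, w
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = ConvEncoder(h, w, cfg.base_width, cfg.n_levels, cfg.latent_dim, rng)
        self.decoder = ConvDecoder(h, w, cfg.base_width, cfg.n_levels, cfg.latent_dim, rng)

    def parameters(self):
        return self.encoder.parameters() + self.decoder.parameters()

    def forward(self, x: Tensor) -> Tensor:
        return self.decoder(self.encoder(x))

    def reconstruct_batch(self, pixels: np.ndarray) -> np.ndarray:
        out = self.forward(Tensor(pixels.astype(np.float32)))
        return np.clip(out.data, 0.0, 1.0)

    def reconstruct(self, image: Image) -> Image:
        if image.shape != (self.h, self.w):
            raise ValueError(f"model expects {self.h}x{self.w} images, got {image.shape}")
        return self._reconstruct_single(image)

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(params) != len(arrays):
            raise ValueError("checkpoint/model parameter count mismatch")
        for p, a in zip(params, arrays):
            p.data = a.astype(np.float32)

    def config_dict(self) -> dict:
        return {"h": self.h, "w": self.w, "train_config": self.cfg.to_dict()}


def train_ae(images: list[Image], cfg: TrainConfig,
             model: AEModel | None = None) -> AEModel:
    """Fit the autoencoder on normal images; returns the fitted model.

    One seed controls weight init, batch order and corruption noise, so two
    runs with equal seed and config produce equal weights.
    """
    batch = stack_images(images)
    n, _, h, w = batch.shape
    if model is None:
        model = AEModel(h, w, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    for _ in range(cfg.epochs):
        for idx in minibatches(n, cfg.batch_size, rng):
            clean = batch[idx]
            noisy = clean
            if cfg.corruption_noise_sigma > 0:
                noisy = clean + rng.normal(
                    0, cfg.corruption_noise_sigma, clean.shape
                ).astype(np.float32)
            out = model.forward(Tensor(noisy))
            loss = pnorm_loss(out - Tensor(clean), cfg.p_norm)
            check_finite(loss.item(), "AE training")
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model
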