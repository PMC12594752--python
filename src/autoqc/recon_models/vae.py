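"""Variational autoencoder baseline.

The encoder emits a diagonal Gaussian posterior (mu, log sigma^2); training
minimises the p-norm reconstruction term plus the closed-form KL divergence
to the standard-normal prior, weighted by ``kl_weight``.  Inference decodes
from the posterior mean so reconstructions are deterministic.
"""

from __future__ import annotations

import numpy as np

from ..io_datasets import Image
from ..nn import Adam, Linear, Tensor
from .base import (
    ReconstructionModel,
    TrainConfig,
    check_finite,
    minibatches,
    pnorm_loss,
    stack_images,
)
from .nets import ConvDecoder, ConvEncoder

__all__ = ["VAEModel", "train_vae", "kl_standard_normal"]


def kl_standard_normal(mu: Tensor, logvar: Tensor) -> Tensor:
    """Mean over the batch of KL(N(mu, diag(e^logvar)) || N(0, I)).

    Closed form per latent dimension: 1/2 (mu^2 + sigma^2 - log sigma^2 - 1),
    summed over dimensions.  Parameterising through log sigma^2 keeps the
    variance structurally positive.
    """
    per_dim = 0.5 * (mu**2.0 + logvar.exp() - logvar - 1.0)
    return per_dim.sum(axis=1).mean()


class VAEModel(ReconstructionModel):
    name = "vae"

    def __init__(self, h: int, w: int, cfg: TrainConfig):
        self.h, self.w = h, w
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        # shared conv trunk; two linear heads for mu and log-variance
        self.encoder = ConvEncoder(h, w, cfg.base_width, cfg.n_levels, cfg.latent_dim, rng)
        self.fc_logvar = Linear(self.encoder.flat_dim, cfg.latent_dim, rng)
        self.decoder = ConvDecoder(h, w, cfg.base_width, cfg.n_levels, cfg.latent_dim, rng)

    def parameters(self):
        return (
            self.encoder.parameters()
            + self.fc_logvar.parameters()
            + self.decoder.parameters()
        )

    def encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        feats = self.encoder.features(x)
        return self.encoder.fc(feats), self.fc_logvar(feats)

    def reconstruct_batch(self, pixels: np.ndarray) -> np.ndarray:
        mu, _ = self.encode(Tensor(pixels.astype(np.float32)))
        out = self.decoder(mu)
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


def train_vae(images: list[Image], cfg: TrainConfig,
              model: VAEModel | None = None) -> VAEModel:
    """Fit the VAE on normal images (reparameterised sampling during
    training, mean code at inference)."""
    batch = stack_images(images)
    n, _, h, w = batch.shape
    if model is None:
        model = VAEModel(h, w, cfg)
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
            mu, logvar = model.encode(Tensor(noisy))
            eps = Tensor(rng.standard_normal(mu.shape).astype(np.float32))
            z = mu + (logvar * 0.5).exp() * eps
            out = model.decoder(z)
            loss = pnorm_loss(out - Tensor(clean), cfg.p_norm)
            if cfg.kl_weight > 0:
                loss = loss + cfg.kl_weight * kl_standard_normal(mu, logvar)
            check_finite(loss.item(), "VAE training")
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model
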