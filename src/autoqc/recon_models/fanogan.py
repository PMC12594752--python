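"""f-AnoGAN baseline: WGAN-GP on normal images, then an encoder into the
generator's latent space.

Training step 1 fits generator G and critic D with the Wasserstein objective
plus a gradient penalty on interpolates between real and generated images.
Step 2 freezes G and D and fits an encoder E minimising the izi_f loss: the
mean-squared image residual between x and G(E(x)) plus ``kappa`` times the
mean-squared residual in the critic's penultimate feature space.
Reconstruction is G(E(x)).

The gradient penalty needs d/dweights of the critic's input gradient.  The
input gradient is built here as an explicit composition of differentiable
primitives — the adjoint of each conv is a conv with flipped, channel-swapped
kernels, the adjoint of 2x mean pooling is scaled upsampling, and activation
derivative masks enter as constants (exact a.e. for piecewise-linear
activations) — so ordinary first-order backprop through that composition
yields the penalty's weight gradient.
"""

from __future__ import annotations

import numpy as np

from ..io_datasets import Image
from ..nn import Adam, Tensor, avg_pool2d, conv2d, upsample_nearest2d
from .base import (
    ReconstructionModel,
    TrainConfig,
    check_finite,
    minibatches,
    stack_images,
)
from .nets import ConvEncoder, ConvDecoder, Critic

__all__ = ["FAnoGANModel", "train_fanogan", "izi_f_loss", "critic_input_gradient"]


def izi_f_loss(x: np.ndarray, x_rec: np.ndarray,
               f_x: np.ndarray, f_rec: np.ndarray, kappa: float) -> float:
    """Numeric izi_f objective for given tensors.

    Per sample: (1/n)||x - x_rec||^2 + (kappa/n_d)||f(x) - f(x_rec)||^2 with
    n = pixel count and n_d = feature dimensionality; averaged over the batch.
    """
    x = np.asarray(x, dtype=np.float64)
    x_rec = np.asarray(x_rec, dtype=np.float64)
    f_x = np.asarray(f_x, dtype=np.float64)
    f_rec = np.asarray(f_rec, dtype=np.float64)
    n = np.prod(x.shape[1:])
    n_d = np.prod(f_x.shape[1:])
    img_term = ((x - x_rec) ** 2).reshape(x.shape[0], -1).sum(axis=1) / n
    feat_term = ((f_x - f_rec) ** 2).reshape(x.shape[0], -1).sum(axis=1) / n_d
    return float(np.mean(img_term + kappa * feat_term))


def critic_input_gradient(critic: Critic, x: np.ndarray) -> Tensor:
    """d D(x) / d x as a Tensor differentiable w.r.t. the critic weights."""
    slope = Critic.SLOPE
    h = Tensor(x.astype(np.float32))
    masks = []
    shapes = [h.shape]
    # forward, recording activation-derivative masks (constants)
    for conv in critic.convs:
        pre = conv(h)
        masks.append(np.where(pre.data > 0, 1.0, slope).astype(np.float32))
        h = Tensor(pre.data * masks[-1])
        shapes.append(h.shape)
        h = avg_pool2d(h)
    n = x.shape[0]
    # backward pass written with differentiable primitives
    g = Tensor(np.ones((n, 1), dtype=np.float32)) @ critic.fc.w.transpose((1, 0))
    last = shapes[-1]  # pre-pool shape of the deepest activation
    g = g.reshape(n, last[1], last[2] // 2, last[3] // 2)
    for conv, mask in zip(reversed(critic.convs), reversed(masks)):
        g = upsample_nearest2d(g) * 0.25  # adjoint of 2x mean pooling
        g = g * Tensor(mask)
        g = conv2d(g, conv.w.swap_io().flip_spatial())  # adjoint of same-pad conv
    return g


def gradient_penalty(critic: Critic, interp: np.ndarray) -> Tensor:
    g = critic_input_gradient(critic, interp)
    norms = ((g**2.0).sum(axis=(1, 2, 3)) + 1e-12).sqrt()
    return ((norms - 1.0) ** 2.0).mean()


class FAnoGANModel(ReconstructionModel):
    name = "fanogan"

    def __init__(self, h: int, w: int, cfg: TrainConfig):
        self.h, self.w = h, w
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.generator = ConvDecoder(h, w, cfg.base_width, cfg.n_levels, cfg.latent_dim, rng)
        self.critic = Critic(h, w, cfg.base_width, cfg.n_levels, rng)
        self.encoder = ConvEncoder(h, w, cfg.base_width, cfg.n_levels, cfg.latent_dim, rng)

    def parameters(self):
        return (
            self.generator.parameters()
            + self.critic.parameters()
            + self.encoder.parameters()
        )

    def reconstruct_batch(self, pixels: np.ndarray) -> np.ndarray:
        z = self.encoder(Tensor(pixels.astype(np.float32)))
        out = self.generator(z)
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


def train_fanogan(images: list[Image], cfg: TrainConfig,
                  model: FAnoGANModel | None = None,
                  encoder_epochs: int | None = None) -> FAnoGANModel:
    """Two-step f-AnoGAN training on normal images.

    ``cfg.epochs`` counts WGAN-GP epochs (``critic_steps`` critic updates per
    generator update); the encoder then trains for ``encoder_epochs``
    (default: same as ``cfg.epochs``) with G and D frozen.
    """
    batch = stack_images(images)
    n, _, h, w = batch.shape
    if model is None:
        model = FAnoGANModel(h, w, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    d = cfg.latent_dim

    g_params = model.generator.parameters()
    d_params = model.critic.parameters()
    opt_g = Adam(g_params, lr=cfg.learning_rate, betas=(0.5, 0.9))
    opt_d = Adam(d_params, lr=cfg.learning_rate, betas=(0.5, 0.9))

    def sample_real(k):
        idx = rng.integers(0, n, size=k)
        return batch[idx]

    bs = min(cfg.batch_size, n)
    for _ in range(cfg.epochs):
        for _ in range(max(n // bs, 1)):
            for _ in range(cfg.critic_steps):
                real = sample_real(bs)
                z = rng.standard_normal((bs, d)).astype(np.float32)
                fake = model.generator(Tensor(z)).data  # constant for critic step
                d_real = model.critic(Tensor(real))
                d_fake = model.critic(Tensor(fake))
                alpha = rng.uniform(size=(bs, 1, 1, 1)).astype(np.float32)
                interp = alpha * real + (1 - alpha) * fake
                loss_d = d_fake.mean() - d_real.mean() + cfg.gp_weight * gradient_penalty(
                    model.critic, interp
                )
                check_finite(loss_d.item(), "f-AnoGAN critic training")
                opt_d.zero_grad()
                opt_g.zero_grad()
                loss_d.backward()
                opt_d.step()
            z = rng.standard_normal((bs, d)).astype(np.float32)
            fake = model.generator(Tensor(z))
            loss_g = -model.critic(fake).mean()
            check_finite(loss_g.item(), "f-AnoGAN generator training")
            opt_g.zero_grad()
            opt_d.zero_grad()
            loss_g.backward()
            opt_g.step()

    # step 2: encoder with G, D frozen
    e_params = model.encoder.parameters()
    opt_e = Adam(e_params, lr=cfg.learning_rate)
    n_pix = float(h * w)
    n_d = float(model.critic.feat_dim)
    for _ in range(encoder_epochs if encoder_epochs is not None else cfg.epochs):
        for idx in minibatches(n, bs, rng):
            x = Tensor(batch[idx])
            z = model.encoder(x)
            x_rec = model.generator(z)
            f_x = model.critic.features(Tensor(batch[idx]))
            f_rec = model.critic.features(x_rec)
            img_term = ((x_rec - x) ** 2.0).sum(axis=(1, 2, 3)) * (1.0 / n_pix)
            feat_term = ((f_rec - f_x) ** 2.0).sum(axis=1) * (cfg.kappa / n_d)
            loss = (img_term + feat_term).mean()
            check_finite(loss.item(), "f-AnoGAN encoder training")
            opt_e.zero_grad()
            opt_g.zero_grad()
            opt_d.zero_grad()
            loss.backward()
            opt_e.step()
    return model
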