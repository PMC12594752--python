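"""Diffusion-based reconstruction: noise schedule, DDPM and patch DDPM.

The forward (noising) process follows the standard variance-preserving
parameterisation  x_t = sqrt(abar_t) x_0 + sqrt(1 - abar_t) eps  with a
monotone linear beta schedule.  The denoiser is a small U-Net f(x_t, t) that
predicts the clean image x_0 directly (not the noise), and reconstruction
uses a single network evaluation at one fixed timestep ``t_test`` instead of
the full reverse chain — for quality control the goal is to project an input
onto the normal-image manifold, not to sample from scratch.

The patch variant (pDDPM) noises one patch at a time while the surrounding
context stays clean, which lets the denoiser exploit global context.  At
inference a sliding patch grid (edge-aligned final row/column) covers the
image and overlapping patch predictions are merged by per-pixel averaging.

Model internals use the [-1, 1] intensity frame; reconstructions are mapped
back to the canonical [0, 1] frame before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_datasets import Image
from .nn import (
    Adam,
    Conv2d,
    Linear,
    Module,
    Tensor,
    avg_pool2d,
    concat,
    sinusoidal_time_embedding,
    upsample_nearest2d,
)
from .recon_models.base import (
    ReconstructionModel,
    TrainConfig,
    check_finite,
    minibatches,
    stack_images,
)
from .scoring import patch_positions

__all__ = [
    "NoiseSchedule",
    "DiffusionConfig",
    "forward_diffuse",
    "UNet",
    "DDPMModel",
    "PDDPMModel",
    "train_ddpm",
    "train_pddpm",
    "reconstruct_ddpm",
    "reconstruct_pddpm",
]


@dataclass
class NoiseSchedule:
    """Monotone beta schedule with cached alpha and cumulative-alpha arrays."""

    beta: np.ndarray
    alpha: np.ndarray = field(init=False)
    alpha_bar: np.ndarray = field(init=False)

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=np.float64)
        if beta.ndim != 1 or beta.size < 1:
            raise ValueError("beta must be a 1-D array")
        if beta.min() <= 0 or beta.max() >= 1:
            raise ValueError("beta values must lie in (0, 1)")
        if np.any(np.diff(beta) < 0):
            raise ValueError("beta schedule must be non-decreasing")
        self.beta = beta
        self.alpha = 1.0 - beta
        self.alpha_bar = np.cumprod(self.alpha)

    @property
    def T(self) -> int:
        return int(self.beta.size)

    @classmethod
    def linear(cls, T: int = 1000, beta_start: float = 1e-4,
               beta_end: float = 2e-2) -> "NoiseSchedule":
        if T < 1:
            raise ValueError("T must be >= 1")
        return cls(beta=np.linspace(beta_start, beta_end, T))


@dataclass
class DiffusionConfig:
    """Inference-time diffusion settings.

    ``t_test`` is the single fixed timestep used for reconstruction;
    ``patch_size``/``patch_stride`` control the pDDPM sliding grid.
    """

    schedule: NoiseSchedule = field(default_factory=NoiseSchedule.linear)
    t_test: int | None = None  # default: T // 2
    patch_size: int | None = None  # default: half the image side
    patch_stride: int | None = None  # default: patch_size // 2
    seed: int = 0

    def __post_init__(self):
        if self.t_test is None:
            self.t_test = self.schedule.T // 2
        if not (1 <= self.t_test <= self.schedule.T):
            raise ValueError(f"t_test must be in [1, {self.schedule.T}]")
        if (
            self.patch_size is not None
            and self.patch_stride is not None
            and self.patch_stride > self.patch_size
        ):
            raise ValueError("patch_stride must not exceed patch_size")

    def resolved_patch(self, h: int, w: int) -> tuple[int, int]:
        size = self.patch_size if self.patch_size is not None else min(h, w) // 2
        stride = self.patch_stride if self.patch_stride is not None else max(size // 2, 1)
        if size > min(h, w):
            raise ValueError("patch_size exceeds image size")
        if stride > size:
            raise ValueError("patch_stride must not exceed patch_size")
        return size, stride


def forward_diffuse(x0, t: int, eps, schedule: NoiseSchedule) -> np.ndarray:
    """One-shot forward noising: sqrt(abar_t) x0 + sqrt(1 - abar_t) eps.

    ``t`` is 1-based.  Operates on raw arrays in whatever intensity frame the
    caller uses; pass ``eps`` explicitly for determinism.
    """
    if not (1 <= t <= schedule.T):
        raise ValueError(f"t must be in [1, {schedule.T}], got {t}")
    x0 = x0.pixels if isinstance(x0, Image) else np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if eps.shape != x0.shape:
        raise ValueError("eps must match x0's shape")
    ab = schedule.alpha_bar[t - 1]
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


class UNet(Module):
    """Small U-Net denoiser f(x_t, t) with sinusoidal time conditioning.

    Each resolution level applies conv + additive time embedding + relu +
    conv + relu; skip connections concatenate encoder features into the
    decoder.  Output is linear (the [-1,1] frame is not squashed).
    """

    TEMB_DIM = 32

    def __init__(self, base: int, levels: int, rng: np.random.Generator, c_in: int = 1):
        widths = [base * 2**l for l in range(levels + 1)]  # last = bottleneck
        self.levels = levels
        self.temb_fc1 = Linear(self.TEMB_DIM, self.TEMB_DIM, rng)
        self.temb_fc2 = Linear(self.TEMB_DIM, self.TEMB_DIM, rng)
        self.enc1 = []
        self.enc2 = []
        self.tproj_enc = []
        prev = c_in
        for c in widths[:-1]:
            self.enc1.append(Conv2d(prev, c, 3, rng))
            self.enc2.append(Conv2d(c, c, 3, rng))
            self.tproj_enc.append(Linear(self.TEMB_DIM, c, rng))
            prev = c
        self.mid1 = Conv2d(prev, widths[-1], 3, rng)
        self.mid_tproj = Linear(self.TEMB_DIM, widths[-1], rng)
        self.mid2 = Conv2d(widths[-1], widths[-1], 3, rng)
        self.dec1 = []
        self.dec2 = []
        self.tproj_dec = []
        prev = widths[-1]
        for c in reversed(widths[:-1]):
            self.dec1.append(Conv2d(prev + c, c, 3, rng))
            self.dec2.append(Conv2d(c, c, 3, rng))
            self.tproj_dec.append(Linear(self.TEMB_DIM, c, rng))
            prev = c
        self.out_conv = Conv2d(prev, 1, 3, rng)

    SLOPE = 0.1  # leaky slope; plain relu risks dead units at this scale

    def __call__(self, x: Tensor, t: np.ndarray) -> Tensor:
        temb = Tensor(sinusoidal_time_embedding(t, self.TEMB_DIM))
        temb = self.temb_fc2(self.temb_fc1(temb).leaky_relu(self.SLOPE))

        def act(h: Tensor) -> Tensor:
            return h.leaky_relu(self.SLOPE)

        def add_t(h: Tensor, proj: Linear) -> Tensor:
            n, c = h.shape[0], h.shape[1]
            return h + proj(temb).reshape(n, c, 1, 1)

        skips = []
        h = x
        for c1, c2, tp in zip(self.enc1, self.enc2, self.tproj_enc):
            h = act(add_t(c1(h), tp))
            h = act(c2(h))
            skips.append(h)
            h = avg_pool2d(h)
        h = act(add_t(self.mid1(h), self.mid_tproj))
        h = act(self.mid2(h))
        for c1, c2, tp, skip in zip(
            self.dec1, self.dec2, self.tproj_dec, reversed(skips)
        ):
            h = concat([upsample_nearest2d(h), skip], axis=1)
            h = act(add_t(c1(h), tp))
            h = act(c2(h))
        return self.out_conv(h)


def _to_internal(pixels: np.ndarray) -> np.ndarray:
    return (2.0 * pixels - 1.0).astype(np.float32)


def _to_canonical(u: np.ndarray) -> np.ndarray:
    return np.clip((u + 1.0) / 2.0, 0.0, 1.0)


class _DiffusionBase(ReconstructionModel):
    def __init__(self, h: int, w: int, train_cfg: TrainConfig, diff_cfg: DiffusionConfig):
        self.h, self.w = h, w
        self.cfg = train_cfg
        self.diff = diff_cfg
        rng = np.random.default_rng(train_cfg.seed)
        self.net = UNet(train_cfg.base_width, train_cfg.n_levels, rng)

    def parameters(self):
        return self.net.parameters()

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
        sched = self.diff.schedule
        return {
            "h": self.h,
            "w": self.w,
            "train_config": self.cfg.to_dict(),
            "diffusion": {
                "T": sched.T,
                "beta_start": float(sched.beta[0]),
                "beta_end": float(sched.beta[-1]),
                "t_test": self.diff.t_test,
                "patch_size": self.diff.patch_size,
                "patch_stride": self.diff.patch_stride,
                "seed": self.diff.seed,
            },
        }


class DDPMModel(_DiffusionBase):
    name = "ddpm"

    def reconstruct_batch(self, pixels: np.ndarray) -> np.ndarray:
        return reconstruct_ddpm(self, pixels, self.diff)


class PDDPMModel(_DiffusionBase):
    name = "pddpm"

    def reconstruct_batch(self, pixels: np.ndarray) -> np.ndarray:
        return np.stack(
            [reconstruct_pddpm(self, pixels[i, 0], self.diff)[None] for i in range(pixels.shape[0])]
        )


def _train_denoiser(model: _DiffusionBase, images, patch: bool):
    cfg, diff = model.cfg, model.diff
    batch = stack_images(images)
    n = batch.shape[0]
    u0_all = _to_internal(batch)
    sched = diff.schedule
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    h, w = model.h, model.w
    if patch:
        psize, _ = diff.resolved_patch(h, w)
    for _ in range(cfg.epochs):
        for idx in minibatches(n, cfg.batch_size, rng):
            u0 = u0_all[idx]
            k = u0.shape[0]
            t = rng.integers(1, sched.T + 1, size=k)
            eps = rng.standard_normal(u0.shape).astype(np.float32)
            ab = sched.alpha_bar[t - 1].astype(np.float32)[:, None, None, None]
            xt = np.sqrt(ab) * u0 + np.sqrt(1.0 - ab) * eps
            if patch:
                # noise only one random patch per sample; context stays clean
                region = np.zeros_like(u0)
                for b in range(k):
                    i0 = int(rng.integers(0, h - psize + 1))
                    j0 = int(rng.integers(0, w - psize + 1))
                    region[b, :, i0 : i0 + psize, j0 : j0 + psize] = 1.0
                net_in = np.where(region > 0, xt, u0)
                pred = model.net(Tensor(net_in), t)
                resid = (pred - Tensor(u0)) * Tensor(region)
                loss = (resid**2.0).sum() / float(region.sum())
            else:
                pred = model.net(Tensor(xt), t)
                loss = ((pred - Tensor(u0)) ** 2.0).mean()
            check_finite(loss.item(), "diffusion training")
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


def train_ddpm(images, cfg: TrainConfig, diff_cfg: DiffusionConfig | None = None,
               model: DDPMModel | None = None) -> DDPMModel:
    """Fit the x0-predicting denoiser with whole-image noising,
    t ~ Uniform{1..T}."""
    batch_shape = stack_images(images).shape
    diff_cfg = diff_cfg if diff_cfg is not None else DiffusionConfig()
    if model is None:
        model = DDPMModel(batch_shape[2], batch_shape[3], cfg, diff_cfg)
    return _train_denoiser(model, images, patch=False)


def train_pddpm(images, cfg: TrainConfig, diff_cfg: DiffusionConfig | None = None,
                model: PDDPMModel | None = None) -> PDDPMModel:
    """Fit the patch-conditioned denoiser: one random patch per sample is
    noised, the loss applies on the patch region only."""
    batch_shape = stack_images(images).shape
    diff_cfg = diff_cfg if diff_cfg is not None else DiffusionConfig()
    if model is None:
        model = PDDPMModel(batch_shape[2], batch_shape[3], cfg, diff_cfg)
    return _train_denoiser(model, images, patch=True)


def reconstruct_ddpm(model: DDPMModel, pixels: np.ndarray,
                     cfg: DiffusionConfig | None = None) -> np.ndarray:
    """Single-evaluation reconstruction at the fixed timestep ``t_test``.

    ``pixels``: (N,1,H,W) in [0,1].  The noise draw is seeded by
    ``cfg.seed`` so identical inputs give identical reconstructions.
    """
    cfg = cfg if cfg is not None else model.diff
    sched = cfg.schedule
    t = cfg.t_test
    if not (1 <= t <= sched.T):
        raise ValueError(f"t_test must be in [1, {sched.T}]")
    u0 = _to_internal(np.asarray(pixels))
    rng = np.random.default_rng(cfg.seed)
    eps = rng.standard_normal(u0.shape).astype(np.float32)
    xt = forward_diffuse(u0, t, eps, sched).astype(np.float32)
    pred = model.net(Tensor(xt), np.full(u0.shape[0], t))
    return _to_canonical(pred.data)


def reconstruct_pddpm(model: PDDPMModel, pixels: np.ndarray,
                      cfg: DiffusionConfig | None = None,
                      denoiser=None) -> np.ndarray:
    """Sliding-patch reconstruction with per-pixel averaging of overlaps.

    ``pixels``: (H, W) in [0,1].  For each grid position only that patch is
    noised at ``t_test`` (clean context), the denoiser runs on the full
    frame, and the patch region of its output is kept.  ``denoiser``
    overrides the network (callable (N,1,H,W), t -> (N,1,H,W) array), which
    is useful for analysing the merge in isolation.
    """
    cfg = cfg if cfg is not None else model.diff
    sched = cfg.schedule
    t = cfg.t_test
    h, w = pixels.shape
    psize, stride = cfg.resolved_patch(h, w)
    rows = patch_positions(h, psize, stride)
    cols = patch_positions(w, psize, stride)
    u0 = _to_internal(np.asarray(pixels))
    rng = np.random.default_rng(cfg.seed)

    inputs = []
    regions = []
    for i0 in rows:
        for j0 in cols:
            eps = rng.standard_normal((psize, psize)).astype(np.float32)
            noised = forward_diffuse(
                u0[i0 : i0 + psize, j0 : j0 + psize], t, eps, sched
            ).astype(np.float32)
            frame = u0.copy()
            frame[i0 : i0 + psize, j0 : j0 + psize] = noised
            inputs.append(frame[None])
            regions.append((i0, j0))
    net_in = np.stack(inputs)
    if denoiser is None:
        out = model.net(Tensor(net_in), np.full(net_in.shape[0], t)).data
    else:
        out = np.asarray(denoiser(net_in, np.full(net_in.shape[0], t)))
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.float64)
    for b, (i0, j0) in enumerate(regions):
        acc[i0 : i0 + psize, j0 : j0 + psize] += out[b, 0, i0 : i0 + psize, j0 : j0 + psize]
        cnt[i0 : i0 + psize, j0 : j0 + psize] += 1.0
    assert cnt.min() >= 1.0
    return _to_canonical(acc / cnt)
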