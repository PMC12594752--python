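"""Convolutional encoder/decoder/critic building blocks.

All nets use 3x3 stride-1 same-padded convolutions with 2x average pooling
(down) or nearest-neighbour upsampling (up).  Channel widths double per level
from ``base_width``, capped at 8x.
"""

from __future__ import annotations

import numpy as np

from ..nn import (
    Conv2d,
    Linear,
    Module,
    Tensor,
    avg_pool2d,
    upsample_nearest2d,
)

__all__ = ["ConvEncoder", "ConvDecoder", "Critic", "level_widths"]


def level_widths(base: int, levels: int) -> list[int]:
    return [min(base * 2**l, base * 8) for l in range(levels)]


def check_divisible(h: int, w: int, levels: int) -> None:
    f = 2**levels
    if h % f or w % f:
        raise ValueError(f"image size {h}x{w} must be divisible by 2^{levels}")


class ConvEncoder(Module):
    """Image (N,1,H,W) -> latent code (N, d)."""

    def __init__(self, h: int, w: int, base: int, levels: int, latent: int,
                 rng: np.random.Generator, c_in: int = 1):
        check_divisible(h, w, levels)
        widths = level_widths(base, levels)
        self.convs = []
        prev = c_in
        for c in widths:
            self.convs.append(Conv2d(prev, c, 3, rng))
            prev = c
        self.flat_dim = widths[-1] * (h >> levels) * (w >> levels)
        self.fc = Linear(self.flat_dim, latent, rng)

    def features(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = avg_pool2d(conv(h).relu())
        return h.reshape(h.shape[0], self.flat_dim)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc(self.features(x))


class ConvDecoder(Module):
    """Latent code (N, d) -> image (N,1,H,W) in [0,1] via a final sigmoid."""

    def __init__(self, h: int, w: int, base: int, levels: int, latent: int,
                 rng: np.random.Generator):
        check_divisible(h, w, levels)
        widths = level_widths(base, levels)[::-1]
        self.h0, self.w0 = h >> levels, w >> levels
        self.c0 = widths[0]
        self.fc = Linear(latent, self.c0 * self.h0 * self.w0, rng)
        self.convs = []
        prev = self.c0
        for c in widths:
            self.convs.append(Conv2d(prev, c, 3, rng))
            prev = c
        self.out_conv = Conv2d(prev, 1, 3, rng)

    def __call__(self, z: Tensor) -> Tensor:
        h = self.fc(z).relu().reshape(z.shape[0], self.c0, self.h0, self.w0)
        for conv in self.convs:
            h = conv(upsample_nearest2d(h)).relu()
        return self.out_conv(h).sigmoid()


class Critic(Module):
    """WGAN critic: image -> scalar; leaky-ReLU convs, no normalisation.

    ``features`` exposes the penultimate activation (flattened final conv
    output) used as the f(.) feature space of the encoder loss.
    """

    SLOPE = 0.2

    def __init__(self, h: int, w: int, base: int, levels: int,
                 rng: np.random.Generator):
        check_divisible(h, w, levels)
        widths = level_widths(base, levels)
        self.convs = []
        prev = 1
        for c in widths:
            self.convs.append(Conv2d(prev, c, 3, rng))
            prev = c
        self.feat_dim = widths[-1] * (h >> levels) * (w >> levels)
        self.fc = Linear(self.feat_dim, 1, rng)

    def features(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = avg_pool2d(conv(h).leaky_relu(self.SLOPE))
        return h.reshape(h.shape[0], self.feat_dim)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc(self.features(x))
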