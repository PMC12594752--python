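"""Parameterised layers and weight initialisation for the numpy NN toolkit."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Conv2d", "Linear", "sinusoidal_time_embedding"]


class Module:
    """Base class: tracks parameter tensors for optimisation/serialisation."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint array shape mismatch")
            p.data = a.astype(np.float32)


class Conv2d(Module):
    """3x3 (or any odd) kernel, stride 1, 'same' padding; He-initialised."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, size=(c_out, c_in, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(0.0, std, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


def sinusoidal_time_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Standard transformer-style sinusoidal embedding of integer timesteps.

    t: (N,) integer array; returns (N, dim) float32.
    """
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    args = np.asarray(t, dtype=np.float64)[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if dim % 2 == 1:
        emb = np.pad(emb, ((0, 0), (0, 1)))
    return emb.astype(np.float32)
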