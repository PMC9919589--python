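"""Layers, modules and the Adam optimiser on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "Sequential", "Adam"]


class Module:
    """Base class: parameter discovery by attribute walk (torch-style)."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

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
                raise ValueError(
                    f"shape mismatch {p.data.shape} vs checkpoint {a.shape}"
                )
            p.data = np.ascontiguousarray(a, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    """Convolution with bias; He-normal init from the supplied RNG."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, pad=self.pad)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


class Adam:
    """Adam with optional linear learning-rate decay schedule."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 2e-4,
        betas: tuple[float, float] = (0.5, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, lr_scale: float = 1.0) -> None:
        self.t += 1
        b1, b2 = self.betas
        lr = self.lr * lr_scale
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_arrays(self) -> list[np.ndarray]:
        return [np.asarray(self.t, dtype=np.int64)] + self.m + self.v

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        self.t = int(arrays[0])
        k = len(self.params)
        if len(arrays) != 1 + 2 * k:
            raise ValueError("optimizer state size mismatch")
        self.m = [np.ascontiguousarray(a, dtype=np.float32) for a in arrays[1 : 1 + k]]
        self.v = [np.ascontiguousarray(a, dtype=np.float32) for a in arrays[1 + k :]]
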