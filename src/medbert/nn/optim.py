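"""Optimization utilities: AdamW with linear warmup and global-norm gradient
clipping, and truncated-normal parameter initialization (std 0.02, the BERT
default)."""

from __future__ import annotations

import numpy as np
from scipy.stats import truncnorm

from .autograd import Tensor


def truncated_normal(
    shape: tuple[int, ...], rng: np.random.Generator, std: float = 0.02
) -> np.ndarray:
    """Normal(0, std) truncated at ±2 std."""
    return truncnorm.rvs(-2.0, 2.0, scale=std, size=shape, random_state=rng)


class AdamW:
    """Adam with decoupled weight decay and optional linear warmup.

    ``params`` maps names to leaf Tensors.  Weight decay is applied to matrix
    parameters only (bias and layer-norm vectors are exempt, the convention
    the decoupled-decay recipe uses).
    """

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 5e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
        warmup_steps: int = 0,
        clip_norm: float | None = 1.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.warmup_steps = warmup_steps
        self.clip_norm = clip_norm
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def lr_at(self, t: int) -> float:
        if self.warmup_steps > 0 and t <= self.warmup_steps:
            return self.lr * t / self.warmup_steps
        return self.lr

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        lr = self.lr_at(self.t)
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(
                    float((p.grad**2).sum())
                    for p in self.params.values()
                    if p.grad is not None
                )
            )
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params.values():
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            v = self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            update = mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and p.data.ndim >= 2:
                update = update + self.weight_decay * p.data
            p.data -= lr * update


__all__ = ["AdamW", "truncated_normal"]
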