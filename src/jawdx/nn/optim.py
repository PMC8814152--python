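"""Parameter initialisation and SGD with momentum for the numpy NN core."""

from __future__ import annotations

import numpy as np

from .autograd import Grads, Tensor

__all__ = ["he_conv", "he_linear", "SGD", "Adam", "params_to_arrays",
           "arrays_to_params"]


def he_conv(rng: np.random.Generator, f: int, c: int, kh: int, kw: int) -> Tensor:
    """He-normal initialised convolution kernel (fan-in = c*kh*kw)."""
    std = np.sqrt(2.0 / (c * kh * kw))
    return Tensor(rng.normal(0.0, std, size=(f, c, kh, kw)))


def he_linear(rng: np.random.Generator, n_in: int, n_out: int) -> Tensor:
    std = np.sqrt(2.0 / n_in)
    return Tensor(rng.normal(0.0, std, size=(n_in, n_out)))


def params_to_arrays(params: dict[str, Tensor]) -> dict[str, np.ndarray]:
    return {k: v.data.copy() for k, v in params.items()}


def arrays_to_params(arrays: dict[str, np.ndarray]) -> dict[str, Tensor]:
    return {k: Tensor(v.copy()) for k, v in arrays.items()}


class SGD:
    """Stochastic gradient descent with classical momentum.

    ``lr_overrides`` maps a parameter-name prefix to a learning rate, so the
    two branches of the network can be trained with their own rates while
    sharing one optimiser (the encoder and classification head use the base
    rate, the segmentation decoder its own).
    """

    def __init__(self, params: dict[str, Tensor], lr: float,
                 momentum: float = 0.9,
                 lr_overrides: dict[str, float] | None = None):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.lr_overrides = dict(lr_overrides or {})
        self._velocity = {k: np.zeros_like(v.data) for k, v in params.items()}

    def _lr_for(self, name: str) -> float:
        for prefix, lr in self.lr_overrides.items():
            if name.startswith(prefix):
                return lr
        return self.lr

    def step(self, grads: Grads) -> None:
        for name, p in self.params.items():
            g = grads.get(p)
            if g is None:
                continue
            v = self._velocity[name]
            v *= self.momentum
            v -= self._lr_for(name) * g
            p.data += v


class Adam:
    """Adam optimiser with optional per-prefix learning-rate overrides.

    Far less sensitive to the raw gradient scale than SGD, which matters for
    the short, small-batch training schedules of the desk-scale profiles.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 lr_overrides: dict[str, float] | None = None):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.lr_overrides = dict(lr_overrides or {})
        self._m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self._v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self._t = 0

    def _lr_for(self, name: str) -> float:
        for prefix, lr in self.lr_overrides.items():
            if name.startswith(prefix):
                return lr
        return self.lr

    def step(self, grads: Grads) -> None:
        self._t += 1
        bc1 = 1.0 - self.b1 ** self._t
        bc2 = 1.0 - self.b2 ** self._t
        for name, p in self.params.items():
            g = grads.get(p)
            if g is None:
                continue
            m, v = self._m[name], self._v[name]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self._lr_for(name) * (m / bc1) / \
                (np.sqrt(v / bc2) + self.eps)
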