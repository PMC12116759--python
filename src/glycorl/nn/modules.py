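"""Neural-network building blocks on top of the autodiff tensor.

Layers hold their parameters as ``Tensor`` leaves with ``requires_grad=True``;
an :class:`Adam` optimizer updates them in place. Initialization and dropout
draw from an explicit ``numpy.random.Generator`` so that training runs are
bit-reproducible under a seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Linear", "MLP", "Adam", "soft_update", "hard_update"]


class Linear:
    """Affine layer y = x W + b with He-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / n_in)
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """ReLU multilayer perceptron with optional inverted dropout.

    ``hidden`` lists the hidden-layer widths; the output layer is linear.
    Dropout (probability ``dropout_p``) is applied after each hidden
    activation only when ``train=True`` is passed to the forward call.
    """

    def __init__(
        self,
        n_in: int,
        hidden: list[int],
        n_out: int,
        rng: np.random.Generator,
        dropout_p: float = 0.0,
        final_activation: bool = False,
    ):
        sizes = [n_in] + list(hidden) + [n_out]
        self.layers = [Linear(sizes[i], sizes[i + 1], rng) for i in range(len(sizes) - 1)]
        self.dropout_p = float(dropout_p)
        self.final_activation = final_activation
        self._rng = rng

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        h = x
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i < last or self.final_activation:
                h = h.relu()
                if train and self.dropout_p > 0.0:
                    keep = 1.0 - self.dropout_p
                    mask = (self._rng.random(h.shape) < keep) / keep
                    h = h * Tensor(mask)
        return h

    @property
    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters]


class Adam:
    """Adam optimizer over a fixed parameter list; clears grads after step."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g**2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def soft_update(target_params: list[Tensor], online_params: list[Tensor], rate: float) -> None:
    """Polyak averaging: target <- (1 - rate) * target + rate * online."""
    for tp, op in zip(target_params, online_params):
        tp.data *= 1.0 - rate
        tp.data += rate * op.data


def hard_update(target_params: list[Tensor], online_params: list[Tensor]) -> None:
    for tp, op in zip(target_params, online_params):
        tp.data = op.data.copy()
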