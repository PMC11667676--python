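"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = ["Module", "Linear", "LayerNorm", "GRU", "dropout"]


class Module:
    """Base class: tracks parameters registered as Tensor attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, s in zip(params, state):
            p.data[...] = s


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class GRU(Module):
    """Single-direction gated recurrent unit layer.

    Pad positions are handled by gating: where ``mask`` is 0 the hidden
    state is carried through unchanged, so the final state equals the state
    at each sequence's true length.
    """

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        h = hidden_dim
        self.w_z = Linear(in_dim + h, h, rng)
        self.w_r = Linear(in_dim + h, h, rng)
        self.w_n = Linear(in_dim + h, h, rng)
        self.hidden_dim = h

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """x: (B, L, D); mask: (B, L) float {0,1}. Returns final state (B, H)."""
        bsz, length, _ = x.shape
        h = Tensor(np.zeros((bsz, self.hidden_dim)))
        for t in range(length):
            xt = x[:, t, :]
            m = Tensor(mask[:, t][:, None])
            xh = concat([xt, h], axis=-1)
            z = self.w_z(xh).sigmoid()
            r = self.w_r(xh).sigmoid()
            n = self.w_n(concat([xt, r * h], axis=-1)).tanh()
            h_new = (1.0 - z) * n + z * h
            h = m * h_new + (1.0 - m) * h
        return h


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate is 0."""
    if not training or rate <= 0.0 or rng is None:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep
    return x * Tensor(mask)
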