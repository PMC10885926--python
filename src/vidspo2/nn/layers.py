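"""Minimal neural-network layer library on top of the autodiff kernel."""

from __future__ import annotations

import numpy as np

from .tensor import (
    Tensor,
    as_tensor,
    avgpool3d,
    concat,
    conv3d,
    instance_norm,
    sigmoid,
    tanh,
)

__all__ = [
    "Module",
    "Parameter",
    "Conv3d",
    "InstanceNorm3d",
    "Linear",
    "LSTM",
    "BiLSTM",
]


def Parameter(array: np.ndarray) -> Tensor:
    return Tensor(np.asarray(array, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and flat state dicts."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for _, value in self._walk():
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        return params

    def _walk(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value._walk(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._walk(prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._walk()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        mine = dict(self._walk())
        missing = set(mine) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, v in mine.items():
            v.data = np.asarray(state[k], dtype=v.data.dtype).reshape(v.data.shape)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Conv3d(Module):
    """3-D convolution layer, stride 1, 'same' padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, kernel, dilation_t: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        kt, kh, kw = kernel
        fan_in = c_in * kt * kh * kw
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(c_out, c_in, kt, kh, kw)))
        self.bias = Parameter(np.zeros(c_out))
        self.dilation_t = dilation_t

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, bias=self.bias, dilation_t=self.dilation_t)


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over (T, H, W) with affine.

    ``relu=True`` fuses a trailing ReLU into the same memory pass.
    """

    def __init__(self, channels: int, eps: float = 1e-5, relu: bool = False):
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1)))
        self.eps = eps
        self.relu = relu

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta, axes=(2, 3, 4),
                             eps=self.eps, fuse_relu=self.relu)


class Linear(Module):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator | None = None,
                 bias_init: float = 0.0):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / f_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(f_in, f_out)))
        self.bias = Parameter(np.full((f_out,), bias_init))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LSTM(Module):
    """Single-layer LSTM; returns the final hidden state (B, H)."""

    def __init__(self, f_in: int, hidden: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        s_x = np.sqrt(1.0 / f_in)
        s_h = np.sqrt(1.0 / hidden)
        self.wx = Parameter(rng.normal(0.0, s_x, size=(f_in, 4 * hidden)))
        self.wh = Parameter(rng.normal(0.0, s_h, size=(hidden, 4 * hidden)))
        b = np.zeros(4 * hidden, dtype=np.float32)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.bias = Parameter(b)
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        hdim = self.hidden
        h = as_tensor(np.zeros((B, hdim), dtype=np.float32))
        c = as_tensor(np.zeros((B, hdim), dtype=np.float32))
        for t in range(T):
            gates = x[:, t, :] @ self.wx + h @ self.wh + self.bias
            i = sigmoid(gates[:, 0:hdim])
            f = sigmoid(gates[:, hdim:2 * hdim])
            g = tanh(gates[:, 2 * hdim:3 * hdim])
            o = sigmoid(gates[:, 3 * hdim:4 * hdim])
            c = f * c + i * g
            h = o * tanh(c)
        return h


class BiLSTM(Module):
    """Bidirectional LSTM; concatenates the two final hidden states."""

    def __init__(self, f_in: int, hidden: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.fwd = LSTM(f_in, hidden, rng=rng)
        self.bwd = LSTM(f_in, hidden, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h_f = self.fwd(x)
        h_b = self.bwd(x[:, ::-1, :])
        return concat([h_f, h_b], axis=1)


def avgpool(x: Tensor, kernel, stride) -> Tensor:
    return avgpool3d(x, kernel, stride)
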