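"""Neural-network building blocks on top of the autodiff core.

Modules hold :class:`Parameter` leaves and compose into trees; ``state_dict``
round-trips bitwise, which the checkpoint tests rely on. Initialisation is
always driven by an explicit ``numpy.random.Generator`` so that model
construction is reproducible from a seed alone.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concatenate, pad2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery over attributes."""

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            yield from _walk(full, value)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _walk(prefix, value):
    if isinstance(value, Parameter):
        yield prefix, value
    elif isinstance(value, Module):
        yield from value.named_parameters(prefix + ".")
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _walk(f"{prefix}.{i}", v)
    elif isinstance(value, dict):
        for k, v in value.items():
            yield from _walk(f"{prefix}.{k}", v)


class ModuleList(Module):
    def __init__(self, modules=()):
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m):
        self.items.append(m)


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    """Affine map on the last axis: y = x @ W + b, W of shape (in, out)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(xavier_uniform(rng, in_features, out_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.dim = dim
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        y = xc * (var + self.eps) ** -0.5
        return y * self.gamma + self.beta


class Mlp(Module):
    """Two-layer feed-forward block with GELU, hidden width = ratio * dim."""

    def __init__(self, dim: int, mlp_ratio: float, rng: np.random.Generator):
        hidden = int(round(dim * mlp_ratio))
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class Conv3x3(Module):
    """3x3 same-padding convolution on channel-last (B, h, w, c) tensors.

    Implemented as nine shifted 1x1 projections over a zero-padded input so the
    backward pass falls out of the autodiff core.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = 9 * in_channels
        self.weight = Parameter(
            xavier_uniform(rng, fan_in, out_channels, shape=(3, 3, in_channels, out_channels))
        )
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        _, h, w, _ = x.shape
        padded = pad2d(x, 1)
        out = None
        for dy in range(3):
            for dx in range(3):
                piece = padded[:, dy:dy + h, dx:dx + w, :] @ self.weight[dy, dx]
                out = piece if out is None else out + piece
        return out + self.bias


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999 by default, no weight decay)."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def global_average_pool(x: Tensor, axes) -> Tensor:
    return x.mean(axis=axes)


def concat_last(tensors) -> Tensor:
    return concatenate(tensors, axis=-1)
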