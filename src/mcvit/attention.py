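"""Self-attention families used by the three CAST branches.

Three mechanisms share one scaled-attention core:

* :class:`MultiHeadSelfAttention` (MSA) — full global attention, used by the
  global-guided branch and by the slide-level transformer.
* :class:`WindowMSA` — attention inside non-overlapping ``window x window``
  token windows with a learned relative position bias; the shifted variant
  cyclically rolls the grid by ``window // 2`` and masks attention between
  tokens that wrapped around from opposite grid edges.
* :class:`SpatialReductionAttention` (SRA) — queries at full resolution while
  keys/values come from an ``sr_ratio``-fold patch-merged copy of the grid.

All blocks are shape-preserving maps on token grids. Scores are scaled by
``1/sqrt(head_dim)`` by default; ``attn_scale="inv_dim"`` selects a literal
``1/head_dim`` scaling for comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, as_tensor, roll2d
from ._nn import LayerNorm, Linear, Mlp, Module, Parameter

MASK_VALUE = -1e9


@dataclass
class AttentionConfig:
    """Hyperparameters of one attention block family.

    dim must be divisible by n_heads; shift must be smaller than window;
    sr_ratio must divide both grid sides it is applied to.
    """

    dim: int
    n_heads: int
    window: int = 8
    shift: int = 0
    sr_ratio: int = 1
    mlp_ratio: float = 4.0
    attn_scale: str = "rsqrt"

    def __post_init__(self):
        if self.dim % self.n_heads:
            raise ValueError(f"dim={self.dim} not divisible by n_heads={self.n_heads}")
        if self.shift >= self.window:
            raise ValueError(f"shift={self.shift} must be < window={self.window}")
        if self.attn_scale not in ("rsqrt", "inv_dim"):
            raise ValueError(f"unknown attn_scale {self.attn_scale!r}")

    @property
    def head_dim(self) -> int:
        return self.dim // self.n_heads


@dataclass
class TokenGrid:
    """Token sequence retaining its 2D arrangement: data is (B, h, w, c)."""

    data: Tensor

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError(f"TokenGrid data must be 4D (B,h,w,c), got {self.data.shape}")

    @property
    def h(self) -> int:
        return self.data.shape[1]

    @property
    def w(self) -> int:
        return self.data.shape[2]

    @property
    def dim(self) -> int:
        return self.data.shape[3]

    @property
    def n_tokens(self) -> int:
        return self.h * self.w

    @classmethod
    def from_array(cls, arr) -> "TokenGrid":
        return cls(as_tensor(arr))


def scaled_attention(q: Tensor, k: Tensor, v: Tensor, bias=None,
                     attn_scale: str = "rsqrt", return_attn: bool = False):
    """softmax(q k^T * scale + bias) v over the last two axes.

    q, k, v are (..., n, d); bias broadcasts against the (..., n, n) scores.
    Each attention row sums to one by construction.
    """
    for name, t in (("q", q), ("k", k), ("v", v)):
        if not np.all(np.isfinite(t.data)):
            raise ValueError(f"non-finite values in attention input {name}")
    d = q.shape[-1]
    if d < 1:
        raise ValueError("head dimension must be >= 1")
    scale = (1.0 / np.sqrt(d)) if attn_scale == "rsqrt" else (1.0 / d)
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * scale
    if bias is not None:
        scores = scores + bias
    attn = scores.softmax(axis=-1)
    out = attn @ v
    return (out, attn) if return_attn else out


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    b, n, c = x.shape
    return x.reshape(b, n, n_heads, c // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, n, d = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, n, h * d)


class MultiHeadSelfAttention(Module):
    """Classical MSA with fused qkv projection; operates on (B, n, c)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 attn_scale: str = "rsqrt"):
        if dim % n_heads:
            raise ValueError(f"dim={dim} not divisible by n_heads={n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.attn_scale = attn_scale
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        c = self.dim
        qkv = self.qkv(x)
        q = _split_heads(qkv[:, :, :c], self.n_heads)
        k = _split_heads(qkv[:, :, c:2 * c], self.n_heads)
        v = _split_heads(qkv[:, :, 2 * c:], self.n_heads)
        out = scaled_attention(q, k, v, attn_scale=self.attn_scale)
        return self.proj(_merge_heads(out))


def relative_position_index(window: int) -> np.ndarray:
    """(window^2, window^2) lookup into a (2*window-1)^2 bias table.

    Token pairs with equal relative offset share one table entry.
    """
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window),
                                  indexing="ij")).reshape(2, -1)
    rel = coords[:, :, None] - coords[:, None, :]  # (2, n, n) in [-(w-1), w-1]
    rel = rel + (window - 1)
    return rel[0] * (2 * window - 1) + rel[1]


def shifted_window_mask(h: int, w: int, window: int, shift: int) -> np.ndarray:
    """Additive mask (n_windows, n, n): MASK_VALUE where a window mixes tokens
    that wrapped around opposite edges under the cyclic shift."""
    img = np.zeros((h, w), dtype=np.int64)
    region = 0
    slices = (slice(0, -window), slice(-window, -shift), slice(-shift, None))
    for hs in slices:
        for ws in slices:
            img[hs, ws] = region
            region += 1
    wins = (
        img.reshape(h // window, window, w // window, window)
        .transpose(0, 2, 1, 3)
        .reshape(-1, window * window)
    )
    diff = wins[:, :, None] != wins[:, None, :]
    return np.where(diff, MASK_VALUE, 0.0)


class WindowMSA(Module):
    """(Shifted) window attention with relative position bias on (B, h, w, c).

    The grid shape is fixed at construction so the shift mask and bias index
    can be precomputed. When the window covers the whole grid the shift is
    degenerate and is disabled.
    """

    def __init__(self, dim: int, n_heads: int, window: int, grid: tuple[int, int],
                 rng: np.random.Generator, shifted: bool = False,
                 attn_scale: str = "rsqrt"):
        h, w = grid
        if h % window or w % window:
            raise ValueError(
                f"window {window} does not divide grid {grid}; pad the grid to a "
                f"multiple of {window} or choose a dividing window size"
            )
        if dim % n_heads:
            raise ValueError(f"dim={dim} not divisible by n_heads={n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.window = window
        self.grid = (h, w)
        self.attn_scale = attn_scale
        self.shift = window // 2 if (shifted and window < min(h, w)) else 0
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.bias_table = Parameter(
            rng.normal(0.0, 0.02, size=((2 * window - 1) ** 2, n_heads))
        )
        self._bias_index = relative_position_index(window)
        self._mask = (
            shifted_window_mask(h, w, window, self.shift)
            if self.shift > 0 else None
        )

    def _relative_bias(self) -> Tensor:
        n = self.window * self.window
        flat = self.bias_table[self._bias_index.reshape(-1)]  # (n*n, heads)
        return flat.reshape(n, n, self.n_heads).transpose(2, 0, 1)  # (heads, n, n)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        if (h, w) != self.grid:
            raise ValueError(f"expected grid {self.grid}, got {(h, w)}")
        wd = self.window
        if self.shift:
            x = roll2d(x, (-self.shift, -self.shift))
        nwh, nww = h // wd, w // wd
        nw = nwh * nww
        n = wd * wd
        # (B, nw, n, c) windows
        xw = (
            x.reshape(b, nwh, wd, nww, wd, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, nw, n, c)
        )
        qkv = self.qkv(xw)
        q = qkv[:, :, :, :c].reshape(b, nw, n, self.n_heads, c // self.n_heads)
        k = qkv[:, :, :, c:2 * c].reshape(b, nw, n, self.n_heads, c // self.n_heads)
        v = qkv[:, :, :, 2 * c:].reshape(b, nw, n, self.n_heads, c // self.n_heads)
        q = q.transpose(0, 1, 3, 2, 4)  # (B, nw, heads, n, d)
        k = k.transpose(0, 1, 3, 2, 4)
        v = v.transpose(0, 1, 3, 2, 4)
        bias = self._relative_bias()  # (heads, n, n) broadcasts over (B, nw)
        if self._mask is not None:
            bias = bias + Tensor(self._mask[None, :, None, :, :])
        out = scaled_attention(q, k, v, bias=bias, attn_scale=self.attn_scale)
        out = out.transpose(0, 1, 3, 2, 4).reshape(b, nw, n, c)
        out = (
            out.reshape(b, nwh, nww, wd, wd, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h, w, c)
        )
        if self.shift:
            out = roll2d(out, (self.shift, self.shift))
        return self.proj(out)


class SpatialReductionAttention(Module):
    """SRA: queries at full resolution, keys/values from a patch-merged copy.

    With ``sr_ratio == 1`` the reduction is the identity and the operator
    coincides with MSA (up to the q/kv projection layout).
    """

    def __init__(self, dim: int, n_heads: int, sr_ratio: int, grid: tuple[int, int],
                 rng: np.random.Generator, attn_scale: str = "rsqrt"):
        h, w = grid
        if h % sr_ratio or w % sr_ratio:
            raise ValueError(f"sr_ratio {sr_ratio} does not divide grid {grid}")
        if dim % n_heads:
            raise ValueError(f"dim={dim} not divisible by n_heads={n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.sr_ratio = sr_ratio
        self.grid = (h, w)
        self.attn_scale = attn_scale
        self.q = Linear(dim, dim, rng)
        self.kv = Linear(dim, 2 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        if sr_ratio > 1:
            self.reduce = Linear(sr_ratio * sr_ratio * dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        if (h, w) != self.grid:
            raise ValueError(f"expected grid {self.grid}, got {(h, w)}")
        r = self.sr_ratio
        q = _split_heads(self.q(x.reshape(b, h * w, c)), self.n_heads)
        if r > 1:
            red = (
                x.reshape(b, h // r, r, w // r, r, c)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(b, (h // r) * (w // r), r * r * c)
            )
            src = self.reduce(red)
        else:
            src = x.reshape(b, h * w, c)
        kv = self.kv(src)
        k = _split_heads(kv[:, :, :c], self.n_heads)
        v = _split_heads(kv[:, :, c:], self.n_heads)
        out = scaled_attention(q, k, v, attn_scale=self.attn_scale)
        return self.proj(_merge_heads(out)).reshape(b, h, w, c)


class GlobalBlock(Module):
    """Pre-norm transformer block: x + MSA(LN(x)), then + MLP(LN(.)).

    Operates on (B, n, c) sequences; :meth:`forward_grid` adapts token grids.
    """

    def __init__(self, dim: int, n_heads: int, mlp_ratio: float,
                 rng: np.random.Generator, attn_scale: str = "rsqrt"):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng, attn_scale)
        self.ln2 = LayerNorm(dim)
        self.mlp = Mlp(dim, mlp_ratio, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.attn(self.ln1(x)) + x
        return self.mlp(self.ln2(x)) + x

    def forward_grid(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        return self.forward(x.reshape(b, h * w, c)).reshape(b, h, w, c)


class LocalBlock(Module):
    """Two successive window-attention sub-blocks (plain then shifted),
    each followed by an MLP, all pre-norm with residuals."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: float, window: int,
                 grid: tuple[int, int], rng: np.random.Generator,
                 attn_scale: str = "rsqrt"):
        window = min(window, *grid)
        self.ln1 = LayerNorm(dim)
        self.wmsa = WindowMSA(dim, n_heads, window, grid, rng, shifted=False,
                              attn_scale=attn_scale)
        self.ln2 = LayerNorm(dim)
        self.mlp1 = Mlp(dim, mlp_ratio, rng)
        self.ln3 = LayerNorm(dim)
        self.swmsa = WindowMSA(dim, n_heads, window, grid, rng, shifted=True,
                               attn_scale=attn_scale)
        self.ln4 = LayerNorm(dim)
        self.mlp2 = Mlp(dim, mlp_ratio, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.wmsa(self.ln1(x)) + x
        x = self.mlp1(self.ln2(x)) + x
        x = self.swmsa(self.ln3(x)) + x
        return self.mlp2(self.ln4(x)) + x
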