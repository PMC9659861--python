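"""Cross-correlation attention module (CAM).

CAM fuses the same-shape token grids of the three scale branches through a
spatial attention map built from per-position channel inner products:

1. stack the branch features into ``G`` of shape (S, c, h, w), S = 3;
2. a 1x1 convolution (shared across the scale slices) gives ``f1``;
3. the fusion-branch feature ``C`` is the correlation target ``f2``;
4. ``Att[s, x, y] = sigmoid( sum_ch f1[s, ch, x, y] * f2[ch, x, y] )`` — a
   per-spatial-position matrix product (S x c) @ (c x 1), which is the only
   reading under which the attention map is (S, h, w);
5. each scale slice of ``G`` (the un-convolved features) is reweighted by its
   attention map and the slices are re-aggregated by a 3x3 convolution back
   to ``c`` channels.

Attention values lie strictly in (0, 1) (sigmoid range). The channel inner
product is not pre-scaled, so with many channels of large-variance input the
sigmoid can saturate; inputs are typically layer-normalised upstream.

:func:`cam_oracle` recomputes the identical contract with explicit Python
loops over scales, channels and positions (no batched linear algebra); it is
the independent equivalence oracle for :class:`CrossCorrelationAttention`.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, as_tensor, concatenate
from ._nn import Conv3x3, Linear, Module


class CrossCorrelationAttention(Module):
    """CAM over ``n_scales`` same-shape (B, h, w, c) token grids.

    Parameters
    ----------
    channels:
        Per-branch channel count ``c``.
    n_scales:
        Number of scale features fused (3 for the full model; fewer under
        branch ablations, where the module degrades to attention over the
        available slices).
    shared_conv1:
        If True (default) one 1x1 convolution is applied to every scale slice
        (scale axis treated as batch); if False each slice has its own weights.
    """

    def __init__(self, channels: int, rng: np.random.Generator, n_scales: int = 3,
                 shared_conv1: bool = True):
        if n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        self.channels = channels
        self.n_scales = n_scales
        self.shared_conv1 = shared_conv1
        if shared_conv1:
            self.conv1 = Linear(channels, channels, rng)
        else:
            self.conv1 = [Linear(channels, channels, rng) for _ in range(n_scales)]
        self.conv3 = Conv3x3(n_scales * channels, channels, rng)

    def forward(self, feats: list[Tensor]) -> Tensor:
        return self.forward_with_attention(feats)[0]

    def forward_with_attention(self, feats: list[Tensor]):
        """Returns (fused (B, h, w, c), attention (B, S, h, w))."""
        if len(feats) != self.n_scales:
            raise ValueError(f"expected {self.n_scales} scale features, got {len(feats)}")
        shapes = {f.shape for f in feats}
        if len(shapes) != 1:
            raise ValueError(f"scale features must share one shape, got {sorted(shapes)}")
        b, h, w, c = feats[0].shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        # G: (B, S, h, w, c) — scale-stacked spatial features
        G = concatenate([f.reshape(b, 1, h, w, c) for f in feats], axis=1)
        if self.shared_conv1:
            f1 = self.conv1(G)
        else:
            f1 = concatenate(
                [self.conv1[s](G[:, s]).reshape(b, 1, h, w, c) for s in range(self.n_scales)],
                axis=1,
            )
        f2 = feats[-1].reshape(b, 1, h, w, c)  # fusion-branch feature as target
        att = (f1 * f2).sum(axis=-1, keepdims=True).sigmoid()  # (B, S, h, w, 1)
        enhanced = G * att
        # concatenate scale slices along channels: (B, h, w, S*c), scale-major
        merged = enhanced.transpose(0, 2, 3, 1, 4).reshape(b, h, w, self.n_scales * c)
        fused = self.conv3(merged)
        return fused, att.reshape(b, self.n_scales, h, w)


def cam_forward(A, B, C, params: CrossCorrelationAttention) -> np.ndarray:
    """Functional single-sample CAM: inputs (h, w, c) arrays, output (h, w, c)."""
    feats = [as_tensor(x).reshape(1, *np.shape(x)) for x in (A, B, C)]
    out = params(feats)
    return out.data[0]


def cam_oracle(A, B, C, params: CrossCorrelationAttention) -> np.ndarray:
    """Loop-based reference for CAM on one sample.

    A, B, C: (h, w, c) arrays. Uses the parameters of ``params`` but computes
    every step with explicit nested loops; returns the fused (h, w, c) array.
    """
    if not params.shared_conv1:
        raise NotImplementedError("oracle covers the shared-conv1 configuration")
    A, B, C = (np.asarray(x, dtype=np.float64) for x in (A, B, C))
    feats = [A, B, C][3 - params.n_scales:] if params.n_scales < 3 else [A, B, C]
    h, w, c = feats[0].shape
    S = params.n_scales
    W1 = params.conv1.weight.data  # (c, c): out[j] = sum_i x[i] W1[i, j] + b1[j]
    b1 = params.conv1.bias.data
    W3 = params.conv3.weight.data  # (3, 3, S*c, c)
    b3 = params.conv3.bias.data

    G = np.zeros((S, h, w, c))
    for s in range(S):
        G[s] = feats[s]
    f1 = np.zeros_like(G)
    for s in range(S):
        for x in range(h):
            for y in range(w):
                for j in range(c):
                    acc = b1[j]
                    for i in range(c):
                        acc += G[s, x, y, i] * W1[i, j]
                    f1[s, x, y, j] = acc
    f2 = feats[-1]
    att = np.zeros((S, h, w))
    for s in range(S):
        for x in range(h):
            for y in range(w):
                acc = 0.0
                for ch in range(c):
                    acc += f1[s, x, y, ch] * f2[x, y, ch]
                att[s, x, y] = 1.0 / (1.0 + np.exp(-acc))
    merged = np.zeros((h, w, S * c))
    for s in range(S):
        for x in range(h):
            for y in range(w):
                for ch in range(c):
                    merged[x, y, s * c + ch] = att[s, x, y] * G[s, x, y, ch]
    out = np.zeros((h, w, c))
    for x in range(h):
        for y in range(w):
            for j in range(c):
                acc = b3[j]
                for dy in range(3):
                    for dx in range(3):
                        xi, yi = x + dy - 1, y + dx - 1
                        if 0 <= xi < h and 0 <= yi < w:
                            for i in range(S * c):
                                acc += merged[xi, yi, i] * W3[dy, dx, i, j]
                out[x, y, j] = acc
    return out
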