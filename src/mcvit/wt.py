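"""WT: slide-level transformer for thymoma typing.

A slide is encoded as a feature matrix M of shape (m, 769): for each of m
randomly selected patches, the 768-dimensional multi-scale embedding from the
patch classifier is concatenated with one scalar pathological-label prior
(class index normalised to [0, 1] by dividing by 9). The matrix passes
through a 769 -> model_dim input projection (769 is not divisible by the 12
attention heads, so the blocks run at a head-divisible width and the table
width 769 is the interface width), learned absolute position encodings, three
stages of two classical pre-norm transformer blocks (N = 12 heads, MLP
expansion E = 4), a global average pool over tokens, and a fully connected
head over the eight thymoma types (A, AB, B1, B1+B2, B2, B2+B3, B3, TC).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ._autograd import Tensor, as_tensor, no_grad
from ._nn import Linear, Module, ModuleList, Parameter
from .attention import GlobalBlock

THYMOMA_TYPES = ("A", "AB", "B1", "B1+B2", "B2", "B2+B3", "B3", "TC")


@dataclass
class WTConfig:
    n_tokens: int = 512
    stages: int = 3
    blocks_per_stage: int = 2
    n_heads: int = 12
    mlp_ratio: float = 4.0
    model_dim: int = 768
    n_types: int = 8
    use_abs_pos: bool = True
    input_dim: int = 769
    attn_scale: str = "rsqrt"

    def __post_init__(self):
        if self.model_dim % self.n_heads:
            raise ValueError(
                f"model_dim {self.model_dim} not divisible by n_heads {self.n_heads}")
        if self.n_tokens < 1:
            raise ValueError("n_tokens must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FeatureMatrix:
    """One slide's (m, 769) encoding plus the provenance of the sampled rows."""

    data: np.ndarray
    slide_id: str
    source_indices: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] != 769:
            raise ValueError(f"feature matrix must be (m, 769), got {self.data.shape}")


def build_feature_matrix(embeddings, labels, m: int, rng: np.random.Generator,
                         slide_id: str = "", n_label_classes: int = 10) -> FeatureMatrix:
    """Sample m patch rows and append the normalised label prior.

    Sampling is uniform without replacement; when fewer than m patches are
    available it falls back to sampling with replacement. Each row is
    ``[embedding (768) || label / (n_label_classes - 1)]``; embeddings from
    reduced-width models are zero-padded to 768 so the slide-stage interface
    width stays 769 everywhere.
    """
    embeddings = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    if embeddings.ndim != 2 or embeddings.shape[1] > 768:
        raise ValueError(f"embeddings must be (n, <=768), got {embeddings.shape}")
    if embeddings.shape[1] < 768:
        pad = np.zeros((embeddings.shape[0], 768 - embeddings.shape[1]))
        embeddings = np.concatenate([embeddings, pad], axis=1)
    if len(embeddings) != len(labels):
        raise ValueError("embeddings and labels must have equal length")
    if len(embeddings) == 0:
        raise ValueError("at least one patch is required")
    n = len(embeddings)
    idx = rng.choice(n, size=m, replace=n < m)
    scal = labels[idx].astype(np.float64) / (n_label_classes - 1)
    data = np.concatenate([embeddings[idx], scal[:, None]], axis=1)
    return FeatureMatrix(data=data, slide_id=slide_id, source_indices=idx)


class WSITransformer(Module):
    """Slide-typing transformer; forward maps (B, m, 769) to (B, n_types)."""

    def __init__(self, cfg: WTConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.in_proj = Linear(cfg.input_dim, cfg.model_dim, rng)
        if cfg.use_abs_pos:
            self.pos = Parameter(rng.normal(0.0, 0.02, size=(cfg.n_tokens, cfg.model_dim)))
        self.blocks = ModuleList(
            GlobalBlock(cfg.model_dim, cfg.n_heads, cfg.mlp_ratio, rng, cfg.attn_scale)
            for _ in range(cfg.stages * cfg.blocks_per_stage)
        )
        self.head = Linear(cfg.model_dim, cfg.n_types, rng)

    def forward(self, matrix) -> Tensor:
        x = as_tensor(matrix)
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        if x.shape[-1] != self.cfg.input_dim:
            raise ValueError(
                f"feature matrix width must be {self.cfg.input_dim}, got {x.shape[-1]}")
        x = self.in_proj(x)
        if self.cfg.use_abs_pos:
            if x.shape[1] != self.cfg.n_tokens:
                raise ValueError(
                    f"absolute position encodings expect m={self.cfg.n_tokens} "
                    f"tokens, got {x.shape[1]}; disable use_abs_pos for variable m")
            x = x + self.pos
        for block in self.blocks:
            x = block(x)
        pooled = x.mean(axis=1)
        return self.head(pooled)

    def predict(self, matrices, batch_size: int = 8):
        """Returns (type indices (B,), probabilities (B, n_types))."""
        matrices = np.asarray(matrices, dtype=np.float64)
        if matrices.ndim == 2:
            matrices = matrices[None]
        types, probs = [], []
        with no_grad():
            for lo in range(0, len(matrices), batch_size):
                logits = self.forward(matrices[lo:lo + batch_size]).data
                z = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(z)
                probs.append(e / e.sum(axis=1, keepdims=True))
                types.append(np.argmax(logits, axis=1))
        return np.concatenate(types), np.concatenate(probs)


def predict_type(logits) -> int:
    """Argmax thymoma type with lowest-index tie-break."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    return int(np.argmax(logits))
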