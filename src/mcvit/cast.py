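"""CAST: cross attentive scale-aware transformer for patch-level
pathological-information classification.

Three hierarchical branches process co-registered views of one tissue field:

* GGB (global-guided branch) — 10x view, classical MSA blocks;
* LGB (local-guided branch)  — 40x view, windowed/shifted-window blocks;
* FAB (feature aggregation branch) — 20x view, CAS blocks that fuse all three
  branches through CAM followed by spatial-reduction attention.

The per-branch stem patch sizes (8 / 4 / 2 on the 40x / 20x / 10x images) make
the three stage-1 token grids shape-identical, so CAM can correlate them
position by position. After stages 1 and 2 each branch is downsampled by a
2x2 patch merge with a linear projection, halving the grid and (by default)
doubling the channels. The classifier head is a global average pool over the
fusion branch's stage-3 grid followed by a fully connected layer; the
768-dimensional slide-stage embedding concatenates a pooled-and-projected
256-vector per branch (zero-filled for disabled branches).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._autograd import Tensor, as_tensor, concatenate, no_grad
from ._nn import Linear, Module, ModuleList
from .attention import GlobalBlock, LayerNorm, LocalBlock, Mlp, SpatialReductionAttention
from .cam import CrossCorrelationAttention

PATHO_CLASSES = (
    "spindle_epithelial",
    "b1_epithelial",
    "b2_epithelial",
    "b3_epithelial",
    "fibrous_septa",
    "erythrocyte",
    "lymphocyte",
    "perivascular_space",
    "medullary_areas",
    "tumor",
)


@dataclass
class CASTConfig:
    """Architecture hyperparameters; defaults are the full-size model."""

    stage_dims: tuple = (128, 256, 512)
    stage_heads: tuple = (2, 4, 8)
    stage_mlp_ratios: tuple = (8, 4, 4)
    img_sizes: tuple = (64, 128, 256)        # (10x, 20x, 40x) side lengths
    stage1_patch: tuple = (2, 4, 8)          # stem patch per branch (GGB, FAB, LGB)
    merge_patch: int = 2
    blocks_per_stage: int = 2
    n_classes: int = 10
    use_ggb: bool = True
    use_fab: bool = True
    use_lgb: bool = True
    use_cam: bool = True
    embed_dim_out: int = 768
    window: int = 8
    sr_ratios: tuple = (8, 4, 2)
    attn_scale: str = "rsqrt"
    cam_shared_conv1: bool = True

    def __post_init__(self):
        grids = {
            self.img_sizes[0] // self.stage1_patch[0],
            self.img_sizes[1] // self.stage1_patch[1],
            self.img_sizes[2] // self.stage1_patch[2],
        }
        if len(grids) != 1:
            raise ValueError(
                "branch stems must produce one shared grid; got sizes "
                f"{self.img_sizes} with patches {self.stage1_patch}"
            )
        for img, p in zip(self.img_sizes, self.stage1_patch):
            if img % p:
                raise ValueError(f"patch {p} does not divide image side {img}")
        g = grids.pop()
        if g < self.merge_patch ** (len(self.stage_dims) - 1):
            raise ValueError(
                f"stage-1 grid {g} is too small for {len(self.stage_dims)} stages "
                f"with {self.merge_patch}x{self.merge_patch} merging")
        for s in range(len(self.stage_dims)):
            if self.stage_dims[s] % self.stage_heads[s]:
                raise ValueError(
                    f"stage {s}: dim {self.stage_dims[s]} not divisible by "
                    f"heads {self.stage_heads[s]}"
                )
            if g % self.sr_ratios[s]:
                raise ValueError(f"stage {s}: sr_ratio {self.sr_ratios[s]} does not divide grid {g}")
            g //= self.merge_patch
        if not (self.use_ggb or self.use_fab or self.use_lgb):
            raise ValueError("at least one branch must be enabled")
        if self.use_cam and not self.use_fab:
            raise ValueError(
                "use_cam=True requires the FAB branch: CAM correlates against the "
                "fusion-branch feature; disable CAM for FAB-less ablations"
            )
        if self.use_cam and sum((self.use_ggb, self.use_fab, self.use_lgb)) < 2:
            raise ValueError("CAM needs at least two branches; set use_cam=False")
        if self.embed_dim_out % 3:
            raise ValueError("embed_dim_out must be divisible by 3 (one slot per branch)")

    @property
    def stage1_grid(self) -> int:
        return self.img_sizes[2] // self.stage1_patch[2]

    @property
    def n_stages(self) -> int:
        return len(self.stage_dims)

    def grid_at(self, stage: int) -> int:
        return self.stage1_grid // (self.merge_patch ** stage)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PatchLogits:
    """Class scores for one patch; probabilities via softmax over 10 classes."""

    logits: np.ndarray

    @property
    def probs(self) -> np.ndarray:
        z = self.logits - self.logits.max()
        e = np.exp(z)
        return e / e.sum()

    @property
    def predicted_label(self) -> int:
        return predict_label(self.logits)


def predict_label(logits) -> int:
    """Argmax with lowest-index tie-break (np.argmax convention)."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    return int(np.argmax(logits))


class PatchEmbed(Module):
    """Split an image into non-overlapping P x P x 3 patches, flatten, and
    linearly project to ``channels``; output grid is (H/P, W/P, channels)."""

    def __init__(self, patch: int, channels: int, rng: np.random.Generator,
                 in_channels: int = 3):
        self.patch = patch
        self.proj = Linear(patch * patch * in_channels, channels, rng)

    def forward(self, img: Tensor) -> Tensor:
        b, hh, ww, c = img.shape
        p = self.patch
        if hh % p or ww % p:
            raise ValueError(f"patch {p} does not divide image {hh}x{ww}")
        x = (
            img.reshape(b, hh // p, p, ww // p, p, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, hh // p, ww // p, p * p * c)
        )
        return self.proj(x)


class StageDownsample(Module):
    """2x2 patch merge + linear projection: (B,h,w,c) -> (B,h/2,w/2,c_next)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.proj = Linear(4 * c_in, c_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"grid {h}x{w} must have even sides for 2x2 merging")
        merged = (
            x.reshape(b, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h // 2, w // 2, 4 * c)
        )
        return self.proj(merged)


class CASBlock(Module):
    """Fusion-branch block: SRA(LN(CAM(A, B, C))) + C, then + MLP(LN(.)).

    Without CAM (single-branch or fusion-off ablations) the block reduces to
    SRA(LN(C)) + C followed by the MLP sub-block.
    """

    def __init__(self, dim: int, n_heads: int, mlp_ratio: float, sr_ratio: int,
                 grid: tuple[int, int], rng: np.random.Generator,
                 cam: CrossCorrelationAttention | None, attn_scale: str = "rsqrt"):
        self.cam = cam
        self.ln1 = LayerNorm(dim)
        self.sra = SpatialReductionAttention(dim, n_heads, sr_ratio, grid, rng, attn_scale)
        self.ln2 = LayerNorm(dim)
        self.mlp = Mlp(dim, mlp_ratio, rng)

    def forward(self, fusion_prev: Tensor, branch_prevs: list[Tensor]) -> Tensor:
        fused = self.cam(branch_prevs) if self.cam is not None else fusion_prev
        x = self.sra(self.ln1(fused)) + fusion_prev
        return self.mlp(self.ln2(x)) + x


class CAST(Module):
    """Full three-branch patch classifier; see module docstring."""

    def __init__(self, cfg: CASTConfig, rng: np.random.Generator):
        self.cfg = cfg
        dims = cfg.stage_dims
        self.stems = {}
        if cfg.use_ggb:
            self.stems["ggb"] = PatchEmbed(cfg.stage1_patch[0], dims[0], rng)
        if cfg.use_fab:
            self.stems["fab"] = PatchEmbed(cfg.stage1_patch[1], dims[0], rng)
        if cfg.use_lgb:
            self.stems["lgb"] = PatchEmbed(cfg.stage1_patch[2], dims[0], rng)
        n_branches = len(self.stems)

        self.ggb_blocks, self.lgb_blocks, self.fab_blocks = (
            ModuleList(), ModuleList(), ModuleList())
        self.downsamples = {k: ModuleList() for k in self.stems}
        for s in range(cfg.n_stages):
            g = cfg.grid_at(s)
            for _ in range(cfg.blocks_per_stage):
                if cfg.use_ggb:
                    self.ggb_blocks.append(GlobalBlock(
                        dims[s], cfg.stage_heads[s], cfg.stage_mlp_ratios[s], rng,
                        cfg.attn_scale))
                if cfg.use_lgb:
                    self.lgb_blocks.append(LocalBlock(
                        dims[s], cfg.stage_heads[s], cfg.stage_mlp_ratios[s],
                        cfg.window, (g, g), rng, cfg.attn_scale))
                if cfg.use_fab:
                    cam = (CrossCorrelationAttention(
                        dims[s], rng, n_scales=n_branches,
                        shared_conv1=cfg.cam_shared_conv1)
                        if cfg.use_cam else None)
                    self.fab_blocks.append(CASBlock(
                        dims[s], cfg.stage_heads[s], cfg.stage_mlp_ratios[s],
                        cfg.sr_ratios[s], (g, g), rng, cam, cfg.attn_scale))
            if s < cfg.n_stages - 1:
                for k in self.stems:
                    self.downsamples[k].append(StageDownsample(dims[s], dims[s + 1], rng))

        self.head = Linear(dims[-1], cfg.n_classes, rng)
        per_branch = cfg.embed_dim_out // 3
        self.embed_projs = {
            k: Linear(dims[-1], per_branch, rng) for k in self.stems
        }

    # branch order inside CAM: [A (GGB), B (LGB), C (FAB)]
    def _cam_inputs(self, feats: dict) -> list[Tensor]:
        order = [k for k in ("ggb", "lgb", "fab") if k in feats]
        return [feats[k] for k in order]

    def forward(self, img10, img20, img40):
        """Run a batch of triplets; returns (logits (B, K), embedding (B, 768))."""
        cfg = self.cfg
        imgs = {"ggb": img10, "fab": img20, "lgb": img40}
        feats: dict[str, Tensor] = {}
        for k, stem in self.stems.items():
            img = as_tensor(imgs[k])
            expected = {"ggb": cfg.img_sizes[0], "fab": cfg.img_sizes[1],
                        "lgb": cfg.img_sizes[2]}[k]
            if img.ndim != 4 or img.shape[1] != expected or img.shape[2] != expected:
                raise ValueError(
                    f"{k} input must be (B, {expected}, {expected}, 3), got {img.shape}")
            feats[k] = stem(img)

        bi = 0
        for s in range(cfg.n_stages):
            for _ in range(cfg.blocks_per_stage):
                prev = dict(feats)
                if cfg.use_ggb:
                    feats["ggb"] = self.ggb_blocks[bi].forward_grid(prev["ggb"])
                if cfg.use_lgb:
                    feats["lgb"] = self.lgb_blocks[bi](prev["lgb"])
                if cfg.use_fab:
                    feats["fab"] = self.fab_blocks[bi](
                        prev["fab"], self._cam_inputs(prev))
                bi += 1
            if s < cfg.n_stages - 1:
                for k in feats:
                    feats[k] = self.downsamples[k][s](feats[k])

        head_branch = "fab" if cfg.use_fab else ("lgb" if cfg.use_lgb else "ggb")
        pooled_head = feats[head_branch].mean(axis=(1, 2))
        logits = self.head(pooled_head)

        b = logits.shape[0]
        per_branch = cfg.embed_dim_out // 3
        parts = []
        for k in ("ggb", "fab", "lgb"):
            if k in feats:
                parts.append(self.embed_projs[k](feats[k].mean(axis=(1, 2))))
            else:
                parts.append(Tensor(np.zeros((b, per_branch))))
        embedding = concatenate(parts, axis=-1)
        return logits, embedding

    def predict(self, img10, img20, img40, batch_size: int = 64):
        """Inference helper: returns (labels (B,), probs (B, K), embeddings)."""
        n = np.asarray(img10).shape[0]
        labels, probs, embs = [], [], []
        with no_grad():
            for lo in range(0, n, batch_size):
                sl = slice(lo, min(lo + batch_size, n))
                logits, emb = self.forward(
                    np.asarray(img10)[sl], np.asarray(img20)[sl], np.asarray(img40)[sl])
                z = logits.data - logits.data.max(axis=1, keepdims=True)
                e = np.exp(z)
                probs.append(e / e.sum(axis=1, keepdims=True))
                labels.append(np.argmax(logits.data, axis=1))
                embs.append(emb.data)
        return (np.concatenate(labels), np.concatenate(probs), np.concatenate(embs))
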