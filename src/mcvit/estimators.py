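"""scikit-learn style estimators wrapping the two training stages.

:class:`CASTClassifier` fits the patch-level pathological-information
classifier on co-registered image triplets; :class:`WTClassifier` fits the
slide-level typing transformer on stacked feature matrices. Both follow the
sklearn contract (``get_params``/``set_params``, ``fit`` returning ``self``,
fitted attributes with a trailing underscore) so they compose with
``sklearn.base.clone`` and model-selection utilities. The input containers
are domain-shaped rather than flat 2D matrices: X for the patch classifier is
a ``(img10, img20, img40)`` tuple of channel-last image stacks, and X for the
slide classifier is an ``(n_slides, m, 769)`` array.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .cast import CASTConfig
from .training import TrainConfig, train_cast, train_wt
from .wt import WTConfig


def _unpack_triplets(X):
    if not (isinstance(X, (tuple, list)) and len(X) == 3):
        raise ValueError(
            "X must be a (img10, img20, img40) tuple of channel-last image stacks")
    img10, img20, img40 = (np.asarray(a, dtype=np.float64) for a in X)
    if not (len(img10) == len(img20) == len(img40)):
        raise ValueError("the three image stacks must have equal length")
    return img10, img20, img40


class CASTClassifier(ClassifierMixin, BaseEstimator):
    """Patch-level classifier over multi-scale image triplets.

    Parameters mirror the architecture and optimisation configuration;
    defaults are a desk-scale model. ``n_classes`` is inferred from ``y``.
    """

    def __init__(self, stage_dims=(16, 32, 64), stage_heads=(2, 4, 8),
                 stage_mlp_ratios=(2, 2, 2), img_sizes=(16, 32, 64),
                 stage1_patch=(2, 4, 8), window=4, sr_ratios=(2, 2, 1),
                 embed_dim_out=48, use_ggb=True, use_fab=True, use_lgb=True,
                 use_cam=True, epochs=30, lr=2e-3, batch_size=32,
                 val_fraction=0.2, early_stop_val_acc=None, seed=0):
        self.stage_dims = stage_dims
        self.stage_heads = stage_heads
        self.stage_mlp_ratios = stage_mlp_ratios
        self.img_sizes = img_sizes
        self.stage1_patch = stage1_patch
        self.window = window
        self.sr_ratios = sr_ratios
        self.embed_dim_out = embed_dim_out
        self.use_ggb = use_ggb
        self.use_fab = use_fab
        self.use_lgb = use_lgb
        self.use_cam = use_cam
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.early_stop_val_acc = early_stop_val_acc
        self.seed = seed

    def _cast_config(self, n_classes: int) -> CASTConfig:
        return CASTConfig(
            stage_dims=tuple(self.stage_dims), stage_heads=tuple(self.stage_heads),
            stage_mlp_ratios=tuple(self.stage_mlp_ratios),
            img_sizes=tuple(self.img_sizes), stage1_patch=tuple(self.stage1_patch),
            window=self.window, sr_ratios=tuple(self.sr_ratios),
            embed_dim_out=self.embed_dim_out, n_classes=n_classes,
            use_ggb=self.use_ggb, use_fab=self.use_fab, use_lgb=self.use_lgb,
            use_cam=self.use_cam)

    def fit(self, X, y):
        img10, img20, img40 = _unpack_triplets(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n_classes = int(self.classes_.max()) + 1
        rng = np.random.default_rng(self.seed)
        n = len(y)
        order = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n)))
        va, tr = order[:n_val], order[n_val:]
        train = {"img10": img10[tr], "img20": img20[tr], "img40": img40[tr],
                 "label": y[tr]}
        val = {"img10": img10[va], "img20": img20[va], "img40": img40[va],
               "label": y[va]}
        tcfg = TrainConfig(cast_lr=self.lr, cast_batch=self.batch_size,
                           epochs=self.epochs, seed=self.seed,
                           early_stop_val_acc=self.early_stop_val_acc)
        self.model_, self.train_log_ = train_cast(train, val, tcfg,
                                                  self._cast_config(n_classes))
        self.n_classes_ = n_classes
        return self

    def predict(self, X):
        img10, img20, img40 = _unpack_triplets(X)
        labels, _, _ = self.model_.predict(img10, img20, img40,
                                           batch_size=self.batch_size)
        return labels

    def predict_proba(self, X):
        img10, img20, img40 = _unpack_triplets(X)
        _, probs, _ = self.model_.predict(img10, img20, img40,
                                          batch_size=self.batch_size)
        return probs

    def transform(self, X):
        """Per-patch multi-scale embeddings (n, embed_dim_out)."""
        img10, img20, img40 = _unpack_triplets(X)
        _, _, emb = self.model_.predict(img10, img20, img40,
                                        batch_size=self.batch_size)
        return emb


class WTClassifier(ClassifierMixin, BaseEstimator):
    """Slide-typing classifier over (n_slides, m, 769) feature matrices."""

    def __init__(self, model_dim=64, n_heads=4, stages=3, blocks_per_stage=2,
                 mlp_ratio=4.0, use_abs_pos=True, epochs=30, lr=1e-3,
                 batch_size=8, val_fraction=0.2, early_stop_val_acc=None, seed=0):
        self.model_dim = model_dim
        self.n_heads = n_heads
        self.stages = stages
        self.blocks_per_stage = blocks_per_stage
        self.mlp_ratio = mlp_ratio
        self.use_abs_pos = use_abs_pos
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.early_stop_val_acc = early_stop_val_acc
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape[2] != 769:
            raise ValueError(f"X must be (n_slides, m, 769), got {X.shape}")
        self.classes_ = np.unique(y)
        n_types = int(self.classes_.max()) + 1
        cfg = WTConfig(n_tokens=X.shape[1], n_heads=self.n_heads,
                       model_dim=self.model_dim, stages=self.stages,
                       blocks_per_stage=self.blocks_per_stage,
                       mlp_ratio=self.mlp_ratio, n_types=n_types,
                       use_abs_pos=self.use_abs_pos)
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(y))
        n_val = max(1, int(round(self.val_fraction * len(y))))
        va, tr = order[:n_val], order[n_val:]
        tcfg = TrainConfig(wt_lr=self.lr, wt_batch=self.batch_size,
                           epochs=self.epochs, seed=self.seed,
                           early_stop_val_acc=self.early_stop_val_acc)
        self.model_, self.train_log_ = train_wt(X[tr], y[tr], X[va], y[va],
                                                tcfg, cfg)
        self.n_types_ = n_types
        return self

    def predict(self, X):
        types, _ = self.model_.predict(np.asarray(X, dtype=np.float64),
                                       batch_size=self.batch_size)
        return types

    def predict_proba(self, X):
        _, probs = self.model_.predict(np.asarray(X, dtype=np.float64),
                                       batch_size=self.batch_size)
        return probs
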