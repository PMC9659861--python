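"""Losses, optimisation loops and reproducible experiment configuration.

Both sub-networks minimise the multi-class cross-entropy between predicted
probabilities and one-hot ground truth (K = 10 pathological-information
classes for the patch classifier, T = 8 thymoma types for the slide
transformer). Optimisation uses Adam with beta1 = 0.9 and beta2 = 0.999; the
published full-scale profile is 160 epochs at batch 64 / learning rate 2e-3
for CAST and batch 8 / learning rate 1e-3 for WT. Tests and the worked
examples run a desk-scale profile (small dims, few epochs) — see
docs/methods.md for the problem sizes used.

Every loop is deterministic given its seed: shuffling, initialisation and
batching all derive from one ``numpy.random.Generator``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autograd import Tensor, no_grad
from ._nn import Adam, Module
from .cast import CAST, CASTConfig
from .wt import WSITransformer, WTConfig


@dataclass
class TrainConfig:
    """Optimisation settings; defaults are the published full-scale profile."""

    cast_lr: float = 2e-3
    cast_batch: int = 64
    wt_lr: float = 1e-3
    wt_batch: int = 8
    epochs: int = 160
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    lr_schedule: str = "constant"   # or "cosine"
    log_every: int = 0              # steps; 0 disables step logging
    early_stop_val_acc: float | None = None

    def __post_init__(self):
        if min(self.cast_lr, self.wt_lr) < 0:
            raise ValueError("learning rates must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")

    def fingerprint(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class TrainLog:
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    wall_time: float = 0.0
    seed: int = 0
    config_fingerprint: str = ""
    epochs_run: int = 0

    def to_jsonl(self) -> str:
        lines = []
        for i in range(self.epochs_run):
            lines.append(json.dumps({
                "epoch": i,
                "train_loss": self.train_loss[i],
                "train_acc": self.train_acc[i],
                "val_loss": self.val_loss[i],
                "val_acc": self.val_acc[i],
            }))
        return "\n".join(lines) + "\n"


def cross_entropy(probs, onehot) -> float:
    """-sum_k y_k log p_k with probabilities clamped at 1e-12."""
    probs = np.asarray(probs, dtype=np.float64)
    onehot = np.asarray(onehot, dtype=np.float64)
    if probs.shape != onehot.shape:
        raise ValueError(f"length mismatch: probs {probs.shape} vs onehot {onehot.shape}")
    return float(-(onehot * np.log(np.clip(probs, 1e-12, None))).sum())


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of a (B, K) logit tensor against integer labels,
    computed via logsumexp for stability (the training-loop loss)."""
    labels = np.asarray(labels)
    b = logits.shape[0]
    lse = logits.logsumexp(axis=-1)                    # (B,)
    picked = logits[np.arange(b), labels]              # (B,)
    return (lse - picked).mean()


def _lr_at(base: float, epoch: int, total: int, schedule: str) -> float:
    if schedule == "cosine":
        return base * 0.5 * (1.0 + np.cos(np.pi * epoch / max(total, 1)))
    return base


def _run_epochs(model: Module, forward_loss, forward_acc, n_train: int,
                batch_size: int, lr: float, cfg: TrainConfig,
                rng: np.random.Generator) -> TrainLog:
    opt = Adam(model.parameters(), lr=lr, betas=(cfg.beta1, cfg.beta2))
    log = TrainLog(seed=cfg.seed, config_fingerprint=cfg.fingerprint())
    best_acc, best_state = -1.0, None
    t0 = time.time()
    for epoch in range(cfg.epochs):
        opt.lr = _lr_at(lr, epoch, cfg.epochs, cfg.lr_schedule)
        order = rng.permutation(n_train)
        losses, correct = [], 0
        for lo in range(0, n_train, batch_size):
            idx = order[lo:lo + batch_size]
            loss, n_correct = forward_loss(idx)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += n_correct
        val_loss, val_acc = forward_acc()
        log.train_loss.append(float(np.mean(losses)))
        log.train_acc.append(correct / n_train)
        log.val_loss.append(val_loss)
        log.val_acc.append(val_acc)
        log.epochs_run = epoch + 1
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
        if cfg.early_stop_val_acc is not None and val_acc >= cfg.early_stop_val_acc:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    log.wall_time = time.time() - t0
    return log


def _eval_classifier(model, forward, xs, labels, batch_size: int):
    losses, correct = [], 0
    n = len(labels)
    with no_grad():
        for lo in range(0, n, batch_size):
            sl = slice(lo, min(lo + batch_size, n))
            logits = forward(sl)
            loss = softmax_cross_entropy(logits, labels[sl])
            losses.append(float(loss.data) * (sl.stop - sl.start))
            correct += int((np.argmax(logits.data, axis=1) == labels[sl]).sum())
    return float(np.sum(losses) / n), correct / n


def train_cast(train_data: dict, val_data: dict, cfg: TrainConfig,
               cast_cfg: CASTConfig):
    """Train a patch classifier.

    ``train_data``/``val_data`` are dicts with keys ``img10``, ``img20``,
    ``img40`` (float arrays in [0, 1], channel-last) and integer ``label``.
    Returns ``(model, TrainLog)``; the model carries its best-validation
    parameters.
    """
    train_data = {k: np.asarray(v) for k, v in train_data.items()}
    val_data = {k: np.asarray(v) for k, v in val_data.items()}
    for name, d in (("train", train_data), ("val", val_data)):
        if len(d["label"]) == 0:
            raise ValueError(f"{name} split is empty")
    rng = np.random.default_rng(cfg.seed)
    model = CAST(cast_cfg, rng)
    y_tr = np.asarray(train_data["label"])
    y_va = np.asarray(val_data["label"])

    def forward_loss(idx):
        logits, _ = model.forward(train_data["img10"][idx], train_data["img20"][idx],
                                  train_data["img40"][idx])
        loss = softmax_cross_entropy(logits, y_tr[idx])
        n_correct = int((np.argmax(logits.data, axis=1) == y_tr[idx]).sum())
        return loss, n_correct

    def forward_acc():
        return _eval_classifier(
            model,
            lambda sl: model.forward(val_data["img10"][sl], val_data["img20"][sl],
                                     val_data["img40"][sl])[0],
            None, y_va, cfg.cast_batch)

    log = _run_epochs(model, forward_loss, forward_acc, len(y_tr),
                      cfg.cast_batch, cfg.cast_lr, cfg, rng)
    return model, log


def train_wt(matrices, types, val_matrices, val_types, cfg: TrainConfig,
             wt_cfg: WTConfig):
    """Train the slide-typing transformer on stacked (n, m, 769) matrices."""
    matrices = np.asarray(matrices, dtype=np.float64)
    val_matrices = np.asarray(val_matrices, dtype=np.float64)
    y_tr = np.asarray(types)
    y_va = np.asarray(val_types)
    if len(y_tr) == 0 or len(y_va) == 0:
        raise ValueError("empty split")
    rng = np.random.default_rng(cfg.seed)
    model = WSITransformer(wt_cfg, rng)

    def forward_loss(idx):
        logits = model.forward(matrices[idx])
        loss = softmax_cross_entropy(logits, y_tr[idx])
        return loss, int((np.argmax(logits.data, axis=1) == y_tr[idx]).sum())

    def forward_acc():
        return _eval_classifier(
            model, lambda sl: model.forward(val_matrices[sl]),
            None, y_va, cfg.wt_batch)

    log = _run_epochs(model, forward_loss, forward_acc, len(y_tr),
                      cfg.wt_batch, cfg.wt_lr, cfg, rng)
    return model, log


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(path, model: Module, config_obj) -> None:
    """Single-file checkpoint: parameter arrays + embedded config (version 1)."""
    meta = {
        "format_version": 1,
        "model_class": type(model).__name__,
        "config": config_obj.to_dict(),
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path):
    """Rebuild a model from a checkpoint; returns (model, config)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    if meta.get("format_version") != 1:
        raise ValueError(f"unsupported checkpoint version {meta.get('format_version')}")
    rng = np.random.default_rng(0)  # weights are overwritten below
    if meta["model_class"] == "CAST":
        cfg = CASTConfig(**_tuplify(meta["config"]))
        model = CAST(cfg, rng)
    elif meta["model_class"] == "WSITransformer":
        cfg = WTConfig(**meta["config"])
        model = WSITransformer(cfg, rng)
    else:
        raise ValueError(f"unknown model class {meta['model_class']!r}")
    model.load_state_dict(state)
    return model, cfg


def _tuplify(cfg: dict) -> dict:
    out = dict(cfg)
    for k, v in out.items():
        if isinstance(v, list):
            out[k] = tuple(v)
    return out
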