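# mcvit

A two-stage multi-scale vision transformer for thymoma histopathology,
built for researchers working on weakly supervised whole-slide-image (WSI)
classification who want a tested, CPU-runnable reference implementation of
cross-scale attention fusion — plus a synthetic multi-scale data generator
that makes every stage of the pipeline testable without access to clinical
slides.

## The method

Pathologists type thymomas (WHO classes A, AB, B1, B1+B2, B2, B2+B3, B3, TC)
by combining observations across magnifications. `mcvit` mirrors that
workflow in two trainable stages:

**Stage 1 — CAST** (cross attentive scale-aware transformer) classifies
co-registered patch triplets — one tissue field at 10x (64x64), 20x (128x128)
and 40x (256x256) — into ten pathological-information classes (four
epithelial-cell types, fibrous septa, erythrocyte, lymphocyte, perivascular
space, medullary differentiated areas, tumour). Three hierarchical branches
share a 32x32 -> 16x16 -> 8x8 token-grid schedule at 128/256/512 channels:

- global-guided branch (10x): classical pre-norm MSA blocks,
  `A_i = MLP(LN(Ã_i)) + Ã_i` with `Ã_i = MSA(LN(A_{i-1})) + A_{i-1}`;
- local-guided branch (40x): paired window / shifted-window attention blocks
  with learned relative position bias,
  `softmax(QKᵀ/√d + R)V` inside non-overlapping windows;
- feature aggregation branch (20x): the CAS block
  `C̃_i = SRA(LN(CAM(A_{i-1}, B_{i-1}, C_{i-1}))) + C_{i-1}`,
  `C_i = MLP(LN(C̃_i)) + C̃_i`, where SRA draws keys/values from a
  patch-merged copy of the grid.

The cross-correlation attention module (CAM) stacks the branch features
G ∈ R^(3×c×h×w), applies a shared 1x1 convolution, and correlates each scale
slice with the fusion feature per spatial position:
`Att = σ(conv1(reshape([A,B,C])) ⊗ reshape(C)) ∈ R^(3×h×w)` — channel inner
products under a sigmoid — then reweights the slices and re-aggregates them
with a 3x3 convolution. A nested-loop oracle implementation is kept alongside
and the two are equivalence-tested.

**Stage 2 — WT** (WSI transformer) encodes a slide as a feature matrix
M ∈ R^(m×769): m sampled patches, each a 768-d multi-scale embedding from
CAST concatenated with its predicted label scalar (class/9). Three stages of
two classical transformer blocks (12 heads, MLP ratio 4) with absolute
position encodings, a global average pool and a fully connected head produce
the eight type logits. Both stages train with cross-entropy and Adam
(β₁ = 0.9, β₂ = 0.999).

No deep-learning framework is required: the transformer stack runs on a
small reverse-mode autodiff core over NumPy arrays, with gradients verified
against finite differences.

## Worked example

The synthetic generator renders class-dependent 40x scenes and produces the
20x/10x views by exact area averaging, so the three magnifications carry the
complementary information the architecture is designed to fuse. Train the
patch stage on three classes and the slide stage on all eight types
(~1 minute on one CPU):

```python
import numpy as np
from mcvit import CASTClassifier, WTClassifier, SynthConfig
from mcvit.synthetic import (make_triplet, render_scene, sample_patch_labels,
                             synthetic_patch_embeddings)
from mcvit.wt import build_feature_matrix

cfg = SynthConfig(scene_size=64)          # desk-scale triplets: 16/32/64 px
rng = np.random.default_rng(0)

def triplets(classes, n_per):
    imgs = {"img10": [], "img20": [], "img40": []}
    y = []
    for _ in range(n_per):
        for ci, lab in enumerate(classes):
            t = make_triplet(render_scene(lab, rng, cfg), lab)
            for k, img in (("img10", t.img10), ("img20", t.img20),
                           ("img40", t.img40)):
                imgs[k].append(img)
            y.append(ci)
    return tuple(np.asarray(imgs[k]) for k in ("img10", "img20", "img40")), \
        np.asarray(y)

# B3 epithelium vs fibrous septa vs erythrocyte
X_train, y_train = triplets([3, 4, 5], n_per=60)
X_test, y_test = triplets([3, 4, 5], n_per=20)
patch_clf = CASTClassifier(epochs=10, batch_size=32, seed=0,
                           early_stop_val_acc=0.97).fit(X_train, y_train)
acc = (patch_clf.predict(X_test) == y_test).mean()
print(f"patch-stage test accuracy: {acc:.3f}"
      f"  (epochs run: {patch_clf.train_log_.epochs_run})")

def slides(n_per_type, m=64):
    mats, y = [], []
    for t in range(8):
        for _ in range(n_per_type):
            _, labels = sample_patch_labels(t, m, cfg, rng)
            emb = synthetic_patch_embeddings(labels, rng)
            mats.append(build_feature_matrix(emb, labels, m=m, rng=rng).data)
            y.append(t)
    return np.asarray(mats), np.asarray(y)

M_train, t_train = slides(48)
M_test, t_test = slides(8)
slide_clf = WTClassifier(model_dim=64, n_heads=4, mlp_ratio=2.0, epochs=30,
                         seed=0, early_stop_val_acc=0.95).fit(M_train, t_train)
t_acc = (slide_clf.predict(M_test) == t_test).mean()
print(f"slide-stage test accuracy over 8 thymoma types: {t_acc:.3f}")
```

Output:

```
patch-stage test accuracy: 1.000  (epochs run: 7)
slide-stage test accuracy over 8 thymoma types: 0.984
```

The patch stage separates the three classes perfectly within seven epochs —
they differ in fine texture, coarse layout and colour, so any branch helps
and fusion converges fast. The slide stage recovers the thymoma type from
the per-slide mixture of patch labels (feature matrices built here with
ground-truth label priors and the synthetic embedding stand-in); residual
errors come from genuinely overlapping mixed-type compositions.

The estimators follow the scikit-learn contract (`get_params`/`set_params`,
`fit`/`predict`/`predict_proba`, `transform` for embeddings), so they
compose with `sklearn.base.clone` and model-selection tooling. The
underlying library surface (`mcvit.attention`, `mcvit.cam`, `mcvit.cast`,
`mcvit.wt`, `mcvit.training`, `mcvit.metrics`, `mcvit.synthetic`,
`mcvit.io`) is importable directly.

## Command-line pipeline

```bash
mcvit synth      --out data --n-wsis-per-type 4 --patches-per-wsi 64 \
                 --scene-size 64 --seed 0
mcvit train-cast --manifest data/manifest.csv --out run --epochs 10 --seed 0
mcvit eval-cast  --checkpoint run/cast_checkpoint.npz --manifest data/manifest.csv --out run
mcvit embed      --checkpoint run/cast_checkpoint.npz --manifest data/manifest.csv \
                 --out run/features --m 64 --seed 0
mcvit train-wt   --features run/features --manifest data/manifest.csv --out run --epochs 30
mcvit eval-wt    --checkpoint run/wt_checkpoint.npz --features run/features \
                 --manifest data/manifest.csv --out run
mcvit report     --predictions run/wt_predictions.csv --out run/report.json
```

Every command writes its resolved config and seed next to its artifacts, so
any output is regenerable. Datasets are PNG patches plus a CSV manifest
(seed in the header); evaluation reports are JSON with confusion matrix,
macro Rec/Pre/F1, Top-1 and mean per-class accuracy, one-vs-rest ROC/AUC,
Wilson confidence intervals and two-sided McNemar tests.

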